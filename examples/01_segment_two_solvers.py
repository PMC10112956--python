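"""Segment a blockwise-Bernoulli matrix with the exact and greedy solvers.

Builds a small synthetic population: 300 individuals, 60 markers, with
ROH frequency jumping at columns 20 and 40.  Fits the penalized
likelihood estimator exactly (dynamic programming) and greedily (binary
segmentation) at a fixed penalty constant and prints both solutions.
"""

import numpy as np

from rohseg import (
    ChangePointSet,
    PenaltySpec,
    SimulationScenario,
    fit_dp,
    fit_hierarchical,
    simulate,
)

scenario = SimulationScenario(
    family="bernoulli",
    change_points=ChangePointSet((0, 20, 40, 60)),
    params=(0.15, 0.85, 0.30),
)
data = simulate(scenario, n=300, seed=1)

pen = PenaltySpec(lam=1.0, sample_penalty="sqrt_n")
exact = fit_dp(data, pen)
greedy = fit_hierarchical(data, pen)

print(f"true change-points:      {scenario.change_points.points}")
print(f"dynamic programming:     {exact.change_points.points}  "
      f"PL={exact.pl_value:.2f}")
print(f"binary segmentation:     {greedy.change_points.points}  "
      f"PL={greedy.pl_value:.2f}")
for (r, s), est in zip(exact.change_points.blocks(), exact.block_params):
    print(f"  block {r:>2}:{s:<2}  p_hat={est.theta['p']:.3f}")

# The two solvers agree here because the frequency jumps are large; the
# exact PL value can never exceed the greedy one.  Per-block p_hat are
# the population ROH frequencies recovered from the fitted blocks.
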