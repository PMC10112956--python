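"""Model-based synthetic data and evaluation metrics.

The generator reproduces a blockwise-constant study design: ``m``
aligned variables (default 200) partitioned by ``k*`` change-points
(default 10) drawn once, uniformly without replacement from {1,…,m−1}.
Per-block parameters are drawn once per scenario — Bernoulli
probabilities from Uniform(0,1) (open interval, avoiding degenerate
all-0/all-1 blocks), Gaussian means from Normal(0, sd=5) and variances
from Exponential(mean 1) — and then held fixed: every dataset of a
scenario, at every sample size, shares the same change-points and
parameters, so accuracy curves over n reflect sample-size effects only.

Estimation accuracy is summarized by the Jaccard index between the
estimated and true change-point sets (full sets, including the fixed
endpoints 0 and m, hence always > 0) and by the detected count k̂.
:func:`run_study` ties it together: simulate, select λ by FRV, fit, and
tabulate (n, replication, solver, λ, k̂, Jaccard) as a tidy table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataMatrix
from .errors import ValidationError
from .penalty_selection import FRVConfig, frv_select
from .segmentation import ChangePointSet, PenaltySpec

__all__ = [
    "SimulationScenario",
    "draw_scenario",
    "simulate",
    "jaccard",
    "run_study",
]

# sub-stream tags keeping scenario draws independent of data draws
_SCENARIO_STREAM = 0x5C
_DATA_STREAM = 0xDA


@dataclass(frozen=True)
class SimulationScenario:
    """A frozen study condition: family, block structure, and parameters.

    ``params`` holds one value per block: Bernoulli probabilities, or
    ``(mean, var)`` pairs for the Gaussian family.
    """

    family: str
    change_points: ChangePointSet
    params: tuple
    seed: int | None = None

    def __post_init__(self):
        if self.family not in ("bernoulli", "gaussian"):
            raise ValidationError(f"unknown family {self.family!r}")
        if len(self.params) != self.change_points.n_blocks:
            raise ValidationError(
                f"{len(self.params)} parameter entries for "
                f"{self.change_points.n_blocks} blocks"
            )
        flat = []
        for p in self.params:
            if self.family == "bernoulli":
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"bernoulli p={p} outside [0,1]")
                flat.append(float(p))
            else:
                mu, var = p
                if var <= 0:
                    raise ValidationError(f"gaussian variance {var} must be > 0")
                flat.append((float(mu), float(var)))
        object.__setattr__(self, "params", tuple(flat))
        for a, b in zip(self.params, self.params[1:]):
            if a == b:
                warnings.warn(
                    "adjacent blocks share identical parameters; the "
                    "effective change-point set is smaller than specified",
                    stacklevel=2,
                )

    @property
    def m(self) -> int:
        return self.change_points.m

    @property
    def k_star(self) -> int:
        return self.change_points.n_change_points

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "change_points": list(self.change_points.points),
                "params": [list(p) if isinstance(p, tuple) else p
                           for p in self.params],
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationScenario":
        doc = json.loads(text)
        params = tuple(
            tuple(p) if isinstance(p, list) else p for p in doc["params"]
        )
        return cls(
            family=doc["family"],
            change_points=ChangePointSet(tuple(doc["change_points"])),
            params=params,
            seed=doc.get("seed"),
        )


def _param_gaps(family: str, params: tuple) -> np.ndarray:
    if family == "bernoulli":
        return np.abs(np.diff(np.asarray(params)))
    arr = np.asarray(params)  # (blocks, 2): mean, var
    return np.max(np.abs(np.diff(arr, axis=0)), axis=1)


def draw_scenario(
    family: str,
    m: int = 200,
    k_star: int = 10,
    seed: int = 0,
    *,
    gaussian_mean_sd: float = 5.0,
    min_gap: float = 0.0,
    min_width: int = 1,
    max_attempts: int = 1000,
) -> SimulationScenario:
    """Draw and freeze a scenario: change-points and per-block parameters.

    Change-points are ``k_star`` draws without replacement from
    {1,…,m−1}; Bernoulli block probabilities are Uniform on the open unit
    interval; Gaussian blocks get mean ~ Normal(0, gaussian_mean_sd) and
    variance ~ Exponential(mean 1).  The draw stream is independent of
    the data stream, so datasets at different n share one scenario.

    ``min_gap`` and ``min_width`` optionally impose scenario validity by
    rejection: the whole scenario is redrawn (from the same
    distributions) until every block is at least ``min_width`` columns
    wide and every adjacent parameter difference is at least ``min_gap``
    (absolute probability difference for Bernoulli; max of the mean and
    variance differences for Gaussian).  The defaults impose nothing.
    Continuous draws make exactly-equal adjacent parameters a null
    event, but *nearly* equal ones are common and such change-points are
    statistically invisible at practical sample sizes; consistency
    studies use these constraints so that the fixed scenario lies in the
    regime where convergence is observable.
    """
    if not 0 <= k_star < m:
        raise ValidationError(f"need 0 <= k_star < m, got k_star={k_star}, m={m}")
    rng = np.random.default_rng([_SCENARIO_STREAM, seed])
    for _ in range(max_attempts):
        interior = rng.choice(np.arange(1, m), size=k_star, replace=False)
        cps = ChangePointSet.from_interior(interior.tolist(), m)
        n_blocks = cps.n_blocks
        if family == "bernoulli":
            p = rng.uniform(0.0, 1.0, size=n_blocks)
            while np.any((p <= 0.0) | (p >= 1.0)):  # open interval
                bad = (p <= 0.0) | (p >= 1.0)
                p[bad] = rng.uniform(0.0, 1.0, size=int(bad.sum()))
            params = tuple(float(x) for x in p)
        elif family == "gaussian":
            means = rng.normal(0.0, gaussian_mean_sd, size=n_blocks)
            variances = rng.exponential(1.0, size=n_blocks)
            while np.any(variances <= 0.0):
                bad = variances <= 0.0
                variances[bad] = rng.exponential(1.0, size=int(bad.sum()))
            params = tuple(
                (float(a), float(b)) for a, b in zip(means, variances)
            )
        else:
            raise ValidationError(f"unknown family {family!r}")
        widths = np.diff(cps.points)
        if widths.min() < min_width:
            continue
        if n_blocks > 1 and min_gap > 0:
            if _param_gaps(family, params).min() < min_gap:
                continue
        return SimulationScenario(
            family=family, change_points=cps, params=params, seed=seed
        )
    raise ValidationError(
        f"no scenario satisfying min_gap={min_gap}, min_width={min_width} "
        f"found in {max_attempts} draws"
    )


def simulate(
    scenario: SimulationScenario, n: int, seed: int | Sequence[int] = 0
) -> DataMatrix:
    """Draw ``n`` i.i.d. samples of the scenario's block model.

    Within each row, the entries of block j are i.i.d. from the family
    with that block's frozen parameter.
    """
    if n < 1:
        raise ValidationError(f"need n >= 1, got {n}")
    seed_seq = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    rng = np.random.default_rng([_DATA_STREAM, *seed_seq])
    values = np.empty((n, scenario.m))
    for (r, s), par in zip(scenario.change_points.blocks(), scenario.params):
        width = s - r + 1
        if scenario.family == "bernoulli":
            block = (rng.random((n, width)) < par).astype(np.float64)
        else:
            mu, var = par
            block = rng.normal(mu, np.sqrt(var), size=(n, width))
        values[:, r - 1 : s] = block
    return DataMatrix(values=values, family=scenario.family)


def jaccard(C1: ChangePointSet, C2: ChangePointSet) -> float:
    """Jaccard index |C1 ∩ C2| / |C1 ∪ C2| between full change-point sets.

    The sets include the shared endpoints 0 and m, so the index is always
    strictly positive; it equals 1 iff the sets coincide.
    """
    if C1.m != C2.m:
        raise ValidationError(
            f"change-point sets span different m: {C1.m} vs {C2.m}"
        )
    a, b = set(C1.points), set(C2.points)
    return len(a & b) / len(a | b)


def run_study(
    scenario: SimulationScenario,
    n_grid: Sequence[int],
    replications: int,
    solvers: Sequence[str] = ("dp", "hierarchical"),
    frv_cfg: FRVConfig | None = None,
    *,
    pen_template: PenaltySpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate / FRV-select / fit over a grid of sample sizes.

    For each n and replication a fresh dataset is drawn; each solver then
    runs its own FRV scan on it and the selected model is scored against
    the scenario's true change-points.  Returns a tidy table with columns
    ``n, replication, solver, selected_lambda, k_hat, jaccard``.
    """
    if replications < 1:
        raise ValidationError("replications must be >= 1")
    if frv_cfg is None:
        frv_cfg = FRVConfig()
    if pen_template is None:
        pen_template = PenaltySpec(lam=1.0)
    rows = []
    for n in n_grid:
        for rep in range(replications):
            data = simulate(scenario, n, seed=[seed, n, rep])
            for solver in solvers:
                cfg = replace(frv_cfg, solver=solver)
                res = frv_select(data, pen_template, cfg)
                rows.append(
                    {
                        "n": n,
                        "replication": rep,
                        "solver": solver,
                        "selected_lambda": res.selected_lambda,
                        "k_hat": res.k,
                        "jaccard": jaccard(
                            res.selected_model.change_points,
                            scenario.change_points,
                        ),
                    }
                )
    return pd.DataFrame(rows)
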