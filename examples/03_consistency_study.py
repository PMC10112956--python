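"""A scaled-down simulation study: accuracy versus sample size.

For one fixed scenario, simulates replicate datasets at n = 50, 200,
500, selects lambda by FRV for each solver, and summarizes the Jaccard
index between the estimated and true change-point sets.
"""

from rohseg import draw_scenario, run_study

scenario = draw_scenario("bernoulli", m=200, k_star=10, seed=11,
                         min_gap=0.1, min_width=3)
table = run_study(scenario, n_grid=(50, 200, 500), replications=20,
                  solvers=("dp", "hierarchical"), seed=3)

summary = (
    table.groupby(["n", "solver"])
    .agg(median_jaccard=("jaccard", "median"),
         mean_jaccard=("jaccard", "mean"),
         median_k_hat=("k_hat", "median"))
    .round(3)
)
print(summary)

# Medians rise toward 1 (perfect change-point recovery) and k_hat toward
# the true 10 as n grows — the empirical face of the estimators'
# almost-sure convergence; both solvers behave near-identically.
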