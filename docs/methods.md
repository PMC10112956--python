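# Methods

## Model

We observe n independent samples of an m-dimensional random vector whose
coordinates partition into contiguous blocks; within a block the
coordinates are identically distributed with a family parameter that
changes at each block boundary. The change-point set
`C = {0 = c_0 < … < c_k = m}` indexes the boundaries; block j is the
column interval `(c_{j−1}+1):c_j` (1-based, inclusive — the convention
used throughout the library; conversion to 0-based half-open happens
only at the BED boundary). Entries are treated as independent within
and across blocks for likelihood purposes; consistency of the
change-point estimator does not actually require independence across
blocks, only that adjacent blocks differ in parameter.

Supported families and their block negative log-likelihoods at the MLE
(N = observed entries in the block):

- **Bernoulli**: `p̂ = S/N`, `nll = −[S·log p̂ + (N−S)·log(1−p̂)]` with
  the `0·log 0 = 0` convention, so degenerate all-0/all-1 blocks have
  `nll = 0` and stay finite.
- **Gaussian, unknown mean and variance**: `μ̂ = S₁/N`,
  `σ̂² = S₂/N − μ̂²` clamped below by `variance_floor` (default `1e-8`,
  configurable), `nll = (N/2)(log(2π σ̂²) + 1)`. The clamp prevents the
  −∞ likelihood of constant blocks from driving the solvers to isolate
  constant columns.

Missing entries are excluded through the observation mask; all sums run
over observed entries only, which is the natural extension of the
per-entry product likelihood. Sufficient statistics are cumulated over
columns once (cost ∝ n·m), after which any block query costs O(1) from
prefix differences; block costs are never materialized as an m×m table.

## Objective and regularization

`PL(C) = −l(C) + λ·J(n)·R(C)` with `R(C) = Σ_j ρ(block_j)`. `J(n)` must
grow, but slower than n, for consistency; the default is `√n`, with
`log n` and arbitrary callables available. (For the ROH application the
literature is ambiguous between `n` and slower choices; `J(n) = n`
violates the consistency requirement `J(n)/n → 0`, so this package
defaults to `√n` and exposes the choice.)

Two regularizers:

- `ρ ≡ 1`: each block costs λ·J(n); R counts blocks.
- **Physical-span** (`RohRegularization`): with marker positions B (base
  pairs) and scale β = 10⁶, `ρ(r,s) = +∞` if `(B(s)−B(r))/β ≤ T`, else
  `1 / ((B(s)−B(r))/β)` — the reciprocal span in megabases. The +∞ arm
  makes blocks at or below T megabases inadmissible (T defaults to 1% of
  the chromosome span); the reciprocal arm penalizes short blocks more
  than long ones. Reciprocity matters structurally: since
  `1/(a+b) < 1/a + 1/b`, splitting always increases R, the monotonicity
  the consistency theory requires — a regularizer equal to the span
  itself would *reward* splitting (the gaps between blocks leave the
  sum of spans) and shatters constant regions.

Inadmissibility is enforced independently of λ: an infinite ρ yields an
infinite block cost even at λ = 0.

## Solvers

**Dynamic programming** (exact): `F(0) = 0`,
`F(i) = min_{0 ≤ c < i} F(c) + Q((c+1):i)` with
`Q = nll + λ·J(n)·ρ`; backtracking recovers the optimal set. Cost
vectors over all left endpoints for fixed right endpoint are evaluated
vectorized from the prefixes, so the solver is O(m²) with small
constants. If `F(m)` is infinite (every admissible partition contains a
sub-threshold block) the solver raises with a diagnostic pointing at
T versus the marker span.

**Binary segmentation** (greedy): starting from the single interval
`1:m`, each interval `I = r:s` is scored at every candidate
`h_I(c) = PL(r:c) + PL((c+1):s)` (with `PL(∅) = 0`, so `h_I(s) = PL(I)`
appears among the candidates); the interval splits at the minimizer iff
the score *strictly* improves `PL(I)`, and recursion continues on both
halves. Typical cost is O(m·k) block queries.

**Tie-breaking and determinism.** Both solvers take the leftmost
minimizer (`argmin` returns the first), so identical inputs give
identical outputs. The strict-improvement rule means a split that
leaves PL unchanged is rejected. At λ = 0 many segmentations can share
the optimal PL; tests therefore assert the PL value, not the set, in
that regime.

## FRV penalty selection

Scan λ over `{γ, 2γ, …, bγ}`, `b = ⌊λmax/γ⌋` (defaults λmax = 10,
γ = 1/log n; for n ≤ 2 the auto step falls back to λmax/20). Track the
proportion of detected change-points k̂/m, initialized at 1 (its value
at λ = 0); return the model at the first grid point whose proportion
equals the previous one. k̂ counts interior change-points, so the
proportion lives in [0, (m−1)/m] and comparing proportions at fixed m is
an exact integer comparison. If the grid is exhausted without a repeat,
γ is halved and the scan restarts; after `max_halvings` (default 20)
refinements the procedure aborts carrying its full trace. The scan
reuses the prefix statistics across all fits; each grid point is a
fresh solver run. Warnings are emitted in the two degenerate corners
(saturated selected model; selection at the very first grid point).

The rationale: the λ-interval on which the fitted count equals the true
k* grows without bound in n, while the intervals of overfitted counts
shrink to zero. With a step larger than the latter and smaller than the
former, the first repeat lands on k*.

## Synthetic data generator

`draw_scenario` reproduces the reference simulation design: m = 200
columns, k* ∈ {10, 50} change-points drawn once, uniformly without
replacement from {1,…,m−1}; Bernoulli block probabilities ~ U(0,1)
(drawn on the open interval — endpoint draws are redrawn — to avoid
degenerate constant blocks); Gaussian block means ~ N(0, sd = 5) (the
"N(0,5)" of the source literature read as a standard deviation, the
convention of that statistical environment; the sd is a parameter) and
variances ~ Exp(mean 1). A scenario is frozen: every dataset, at every
n, shares its change-points and parameters. Scenario draws and data
draws use independent seed streams, so changing n or the data seed never
changes the scenario. Adjacent blocks are not forced to differ
(exactly-equal continuous draws are a null event, and a validator warns
if they coincide); the studies vary n over 50–500.

**Scenario validity for consistency studies.** Under U(0,1) parameters,
adjacent blocks with a gap below ≈0.05 arise in roughly half of scenario
draws, and a change-point with such a gap is statistically invisible at
n = 500 for *any* method — convergence is real but not yet observable.
The consistency studies therefore fix one scenario drawn with the
explicit rejection options `min_gap = 0.1` (absolute probability
difference) and `min_width = 3` (columns), i.e. the regime in which the
asymptotic behaviour is measurable at the study sizes. The options
default to off, so the bare generator is exactly the reference design.

Evaluation uses the Jaccard index between full change-point sets
(including the shared endpoints 0 and m, hence always positive) and the
detected count k̂. `run_study` runs FRV *per solver* — each solver gets
its own selected λ and model — matching the workflow in which each
algorithm is tuned and evaluated as a unit.

## ROH island calling

Chromosomes are segmented independently (a block cannot cross a
chromosome boundary); the marker map supplies per-column chromosome and
1-based base-pair position, strictly increasing within a chromosome.
Island calling requires a Bernoulli fit. The cutoff is the empirical
quantile (default 95%) of the per-marker block frequencies: by default
each marker contributes its block's p̂, weighting blocks by marker
count, which is directly comparable to per-SNP frequency distributions
from individual-based ROH callers; an unweighted per-block variant is
exposed. Blocks with p̂ at or above the cutoff are flagged and adjacent
flagged blocks merge into a single island (merged p̂ = marker-count-
weighted mean). Island intervals are emitted as BED: 0-based start at
the first marker's base, half-open end one past the last marker's base.
Overlap against an external island list is summarized per chromosome as
base-pair totals and the percentage `100·|a∩b|/|a∪b|` — a base-pair
Jaccard; the union denominator is this package's convention, stated
here because external tools sometimes normalize by one list's length.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full study at m = 200,
k* = 10, n ∈ {50, 200, 500} with 100 replications per n and both
solvers, exhaustive-enumeration checks at m = 10 (512 segmentations per
dataset, 100 Bernoulli + 100 Gaussian datasets), 500 random instances
for the exact-vs-greedy dominance audit, and 100 random marker maps for
the span-threshold audit — sizes chosen so the whole suite completes in
well under a minute per component on one CPU while keeping every check
at its intended statistical resolution. Floating-point comparisons
between independently computed likelihood paths use 1e-9 tolerances;
equality of FRV proportions is exact (integer counts over a common
denominator).

## Known limitations

- The generator emulates the blockwise-i.i.d. model itself: real
  codified SNP matrices carry linkage-induced column dependence, uneven
  marker spacing, and per-individual missingness patterns that the
  generator does not. Passing tests demonstrate correctness of the
  estimators under the model, not robustness to model misspecification.
- Only Bernoulli and Gaussian families are implemented (no Poisson,
  Markov, or covariate models); dependence within blocks is not modelled.
- The dynamic program is the plain O(m²) recursion; no PELT-style
  pruning. For whole-chromosome SNP panels the greedy solver is the
  practical choice, as in the real-data application.
- Change-point locations come without confidence intervals; detection is
  offline only.
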