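"""Automatic penalty-constant selection by First Repeated Value (FRV).

The segmentation estimator is consistent for any fixed λ > 0, but finite-
sample performance depends strongly on it.  FRV removes the usual manual
elbow-plot inspection: scan λ over the grid {γ, 2γ, …, bγ} with
b = ⌊λmax/γ⌋, fit the model at each grid point, and track the *proportion
of detected change-points* k̂/m (a scale-free quantity, always 1 at λ = 0
and decreasing toward 0 as the penalty grows).  The first time the
proportion repeats between consecutive grid points, stop and return that
model and λ.  The rationale: for large n, the λ-interval over which the
true k* is selected grows without bound while the intervals selecting any
overfitted k > k* shrink to zero — so a repeat is overwhelmingly likely
to happen at k*.  If no repeat occurs on the grid, γ is halved and the
scan restarted on the finer grid.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

from .data import DataMatrix
from .errors import ComputationError, ValidationError
from .segmentation import (
    _SOLVERS,
    PenaltySpec,
    SegmentationResult,
    _assemble,
)
from .families import SufficientStatPrefix, build_prefix

__all__ = ["FRVConfig", "FRVResult", "frv_select"]

log = logging.getLogger(__name__)


@dataclass
class FRVConfig:
    """Settings for the FRV scan.

    ``gamma="auto"`` resolves to 1/log(n), the step used in the reference
    simulation design; for n ≤ 2 (where log n ≤ 0.7 makes that step
    unusable) it falls back to ``lambda_max / 20``.  ``max_halvings``
    bounds the grid refinements before aborting.
    """

    lambda_max: float = 10.0
    gamma: float | str = "auto"
    solver: str = "hierarchical"
    max_halvings: int = 20

    def __post_init__(self):
        if self.lambda_max <= 0:
            raise ValidationError("lambda_max must be positive")
        if self.solver not in _SOLVERS:
            raise ValidationError(
                f"unknown solver {self.solver!r}; expected one of "
                f"{tuple(_SOLVERS)}"
            )
        if self.max_halvings < 1:
            raise ValidationError("max_halvings must be >= 1")
        if self.gamma != "auto":
            g = float(self.gamma)
            if not 0 < g <= self.lambda_max:
                raise ValidationError(
                    f"gamma must satisfy 0 < gamma <= lambda_max, got {g}"
                )

    def resolve_gamma(self, n: int) -> float:
        if self.gamma == "auto":
            if n > 2:
                return 1.0 / math.log(n)
            return self.lambda_max / 20.0
        return float(self.gamma)


@dataclass
class FRVResult:
    """Outcome of the FRV scan."""

    selected_lambda: float
    selected_model: SegmentationResult
    trace: list = field(default_factory=list)  # (lambda, k_hat/m) in visit order
    halvings_used: int = 0
    gamma_final: float = 0.0

    @property
    def k(self) -> int:
        return self.selected_model.k


def _fit_at(
    prefix: SufficientStatPrefix,
    pen_template: PenaltySpec,
    n: int,
    lam: float,
    solver: str,
) -> SegmentationResult:
    """One fresh solver run at penalty constant ``lam`` (prefix reused)."""
    pen = pen_template.with_lambda(lam)
    points = _SOLVERS[solver](prefix, pen, n)
    return _assemble(prefix, pen, n, points)


def frv_select(
    data: DataMatrix,
    pen_template: PenaltySpec,
    cfg: FRVConfig | None = None,
    *,
    variance_floor: float = 1e-8,
) -> FRVResult:
    """Select λ by the First Repeated Value procedure.

    Follows the scan literally: the previous proportion starts at 1 (the
    value at λ = 0, where every column is its own block), the grid is
    {γ, 2γ, …, ⌊λmax/γ⌋·γ}, and the first grid point whose detected
    proportion k̂/m equals the previous one is returned.  With m fixed,
    comparing proportions is exactly comparing the integer counts k̂.
    If the grid is exhausted without a repeat, γ is halved and the scan
    restarts; after ``max_halvings`` refinements a :class:`ComputationError`
    carrying the full trace is raised.
    """
    if cfg is None:
        cfg = FRVConfig()
    prefix = build_prefix(data, variance_floor=variance_floor)
    n, m = data.n, data.m
    gamma = cfg.resolve_gamma(n)
    if gamma > cfg.lambda_max:
        raise ValidationError(
            f"gamma={gamma} exceeds lambda_max={cfg.lambda_max}"
        )
    trace: list = []
    halvings = 0
    while True:
        last_prop = 1.0  # the proportion at lambda = 0 is always 1
        b = int(math.floor(cfg.lambda_max / gamma))
        for i in range(1, b + 1):
            lam = i * gamma
            model = _fit_at(prefix, pen_template, n, lam, cfg.solver)
            prop = model.k / m
            trace.append((lam, prop))
            if prop == last_prop:
                if prop == 1.0:
                    warnings.warn(
                        "FRV stopped on a saturated model (every column its "
                        "own block); the penalty grid is likely too coarse "
                        "or lambda_max too small",
                        stacklevel=2,
                    )
                if i == 1:
                    warnings.warn(
                        "FRV selected the very first grid point; the "
                        "repetition against the lambda=0 baseline is "
                        "suspicious — consider a smaller gamma",
                        stacklevel=2,
                    )
                log.info(
                    "FRV selected lambda=%.6g (k=%d) after %d fits, "
                    "%d halvings", lam, model.k, len(trace), halvings,
                )
                return FRVResult(
                    selected_lambda=lam,
                    selected_model=model,
                    trace=trace,
                    halvings_used=halvings,
                    gamma_final=gamma,
                )
            last_prop = prop
        halvings += 1
        if halvings > cfg.max_halvings:
            raise ComputationError(
                "FRV found no repeated change-point count after "
                f"{cfg.max_halvings} grid refinements; trace={trace}"
            )
        gamma /= 2.0
        log.debug("FRV: no repetition on grid, halving gamma to %.6g", gamma)
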