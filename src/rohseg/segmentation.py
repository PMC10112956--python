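"""Penalized-likelihood change-point segmentation.

The model assumes the ``m`` columns of the data split into contiguous
blocks within which the marginal distribution is constant, with a
parameter change at each block boundary.  A change-point set is an
ordered set of indices ``C = {0 = c_0 < c_1 < … < c_k = m}``; block ``j``
spans columns ``(c_{j-1}+1):c_j``.  The estimator minimizes the penalized
likelihood

    PL(C) = −l(C; x^n) + λ · J(n) · R(C),

where ``l`` is the maximized block log-likelihood, ``λ`` a penalty
constant, ``J(n)`` an increasing sample-size weight (consistency requires
it to grow slower than n), and ``R(C) = Σ_j ρ(c_{j-1}+1, c_j)`` an
additive per-block regularizer.  Two regularizers are provided: the
constant ``ρ ≡ 1`` (each block costs the same), and a physical-distance
form for genomic data where ``ρ(r, s)`` is the block span in megabases
and is +∞ below a minimum-span threshold ``T`` — forbidding blocks too
short to be a run-of-homozygosity island.

Two solvers minimize PL:

* :func:`fit_dp` — exact dynamic program over all segmentations,
  ``F(i) = min_c { F(c) + Q((c+1):i) }``, O(m²) block-cost queries;
* :func:`fit_hierarchical` — greedy binary segmentation, recursively
  splitting each interval ``I = r:s`` at the minimizer of
  ``h_I(c) = PL(r:c) + PL((c+1):s)`` while the split strictly improves
  ``PL(I)``; typically O(m·k) queries.

Both break cost ties by choosing the leftmost minimizer, so outputs are
deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

from .data import DataMatrix
from .errors import ComputationError, ValidationError
from .families import BlockEstimate, SufficientStatPrefix, build_prefix

__all__ = [
    "ChangePointSet",
    "ConstantPerBlock",
    "RohRegularization",
    "PenaltySpec",
    "SegmentationResult",
    "rho",
    "block_cost",
    "fit_dp",
    "fit_hierarchical",
    "pl_of",
]


# ---------------------------------------------------------------------------
# change-point sets
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ChangePointSet:
    """Ordered set ``{0 = c_0 < c_1 < … < c_k = m}`` of block boundaries."""

    points: tuple

    def __post_init__(self):
        pts = tuple(int(p) for p in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValidationError("a change-point set needs at least {0, m}")
        if pts[0] != 0:
            raise ValidationError(f"first element must be 0, got {pts[0]}")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValidationError(f"points must be strictly increasing: {pts}")

    @classmethod
    def from_interior(cls, interior: Sequence[int], m: int) -> "ChangePointSet":
        return cls(points=(0, *sorted(int(c) for c in interior), m))

    @property
    def m(self) -> int:
        return self.points[-1]

    @property
    def n_blocks(self) -> int:
        return len(self.points) - 1

    @property
    def n_change_points(self) -> int:
        """Number of interior change-points (block boundaries strictly inside 1:m)."""
        return len(self.points) - 2

    def blocks(self) -> Iterator[tuple]:
        """Yield each block as (r, s), 1-based inclusive."""
        for a, b in zip(self.points, self.points[1:]):
            yield (a + 1, b)

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------
class Regularization:
    """Additive per-block regularizer ρ(r, s)."""

    def rho(self, r: int, s: int) -> float:
        raise NotImplementedError

    def rho_starts(self, s: int) -> np.ndarray:
        """ρ(r, s) for all r = 1..s (index r−1)."""
        raise NotImplementedError

    def rho_ends(self, r: int, m: int) -> np.ndarray:
        """ρ(r, s) for all s = r..m (index s−r)."""
        raise NotImplementedError


class ConstantPerBlock(Regularization):
    """ρ ≡ 1: R(C) counts blocks, so each extra change-point costs λ·J(n)."""

    def rho(self, r: int, s: int) -> float:
        return 1.0

    def rho_starts(self, s: int) -> np.ndarray:
        return np.ones(s)

    def rho_ends(self, r: int, m: int) -> np.ndarray:
        return np.ones(m - r + 1)

    def to_dict(self):
        return {"kind": "constant_per_block"}


class RohRegularization(Regularization):
    """Physical-span regularizer for genomic (single-chromosome) data.

    ``ρ(r, s) = 1 / (|B(s) − B(r)| / β)`` — the reciprocal of the block's
    span in megabases for the default scale ``β = 10⁶`` — and +∞ whenever
    that span is ≤ the threshold ``T`` (in megabases).  Infinite cost
    makes sub-threshold blocks inadmissible, so no fitted block can span
    ≤ T megabases; above the threshold, shorter blocks are penalized more
    than longer ones.  Because 1/(a+b) < 1/a + 1/b, splitting a block
    always increases the total regularization, the monotonicity the
    consistency theory requires of R.

    Parameters
    ----------
    positions : array of int
        Physical base-pair position ``B(j)`` of each column's marker,
        strictly increasing (one chromosome).
    threshold_mb : float
        Minimum admissible block span T, in units of ``scale`` base pairs.
    scale : float
        Base pairs per unit (default 1e6: megabases).
    """

    def __init__(self, positions, threshold_mb: float, scale: float = 1e6):
        positions = np.asarray(positions, dtype=np.float64)
        if positions.ndim != 1 or positions.size < 1:
            raise ValidationError("positions must be a non-empty 1-d array")
        if (np.diff(positions) <= 0).any():
            raise ValidationError("positions must be strictly increasing")
        if (positions < 0).any():
            raise ValidationError("positions must be non-negative")
        if threshold_mb < 0:
            raise ValidationError("threshold T must be >= 0")
        if scale <= 0:
            raise ValidationError("scale beta must be > 0")
        self.positions = positions
        self.threshold_mb = float(threshold_mb)
        self.scale = float(scale)

    @property
    def m(self) -> int:
        return self.positions.size

    def _guard(self, span: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(span <= self.threshold_mb, np.inf, 1.0 / span)

    def rho(self, r: int, s: int) -> float:
        span = abs(self.positions[s - 1] - self.positions[r - 1]) / self.scale
        return math.inf if span <= self.threshold_mb else 1.0 / span

    def rho_starts(self, s: int) -> np.ndarray:
        span = (self.positions[s - 1] - self.positions[:s]) / self.scale
        return self._guard(span)

    def rho_ends(self, r: int, m: int) -> np.ndarray:
        span = (self.positions[r - 1 : m] - self.positions[r - 1]) / self.scale
        return self._guard(np.abs(span))

    def to_dict(self):
        return {
            "kind": "roh",
            "threshold_mb": self.threshold_mb,
            "scale": self.scale,
        }


def rho(reg: Regularization, r: int, s: int) -> float:
    """Evaluate the per-block regularizer ρ(r, s) (1-based inclusive)."""
    if not (1 <= r <= s):
        raise ValidationError(f"need 1 <= r <= s, got r={r}, s={s}")
    return reg.rho(r, s)


# ---------------------------------------------------------------------------
# penalty specification
# ---------------------------------------------------------------------------
_SAMPLE_PENALTIES: dict = {
    "sqrt_n": lambda n: math.sqrt(n),
    "log_n": lambda n: math.log(n),
}


@dataclass
class PenaltySpec:
    """Penalty constant λ, sample-size weight J(n), and regularizer ρ.

    ``sample_penalty`` is ``"sqrt_n"`` (default), ``"log_n"``, or any
    callable ``n -> float``.  Consistency of the estimator requires
    J(n) → ∞ with J(n)/n → 0, which both built-ins satisfy.
    """

    lam: float
    sample_penalty: str | Callable = "sqrt_n"
    reg: Regularization = field(default_factory=ConstantPerBlock)

    def __post_init__(self):
        if self.lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")
        if isinstance(self.sample_penalty, str):
            if self.sample_penalty not in _SAMPLE_PENALTIES:
                raise ValidationError(
                    f"unknown sample_penalty {self.sample_penalty!r}; "
                    f"expected one of {tuple(_SAMPLE_PENALTIES)} or a callable"
                )
        elif not callable(self.sample_penalty):
            raise ValidationError("sample_penalty must be a name or a callable")

    def J(self, n: int) -> float:
        if callable(self.sample_penalty):
            return float(self.sample_penalty(n))
        return _SAMPLE_PENALTIES[self.sample_penalty](n)

    def weight(self, n: int) -> float:
        """The per-unit-ρ penalty λ·J(n)."""
        return self.lam * self.J(n)

    def with_lambda(self, lam: float) -> "PenaltySpec":
        return replace(self, lam=lam)

    @property
    def sample_penalty_label(self) -> str:
        if callable(self.sample_penalty):
            return getattr(self.sample_penalty, "__name__", "custom")
        return self.sample_penalty


def block_cost(
    prefix: SufficientStatPrefix, pen: PenaltySpec, n: int, r: int, s: int
) -> float:
    """Penalized block cost ``Q(r:s) = nll(r:s) + λ·J(n)·ρ(r, s)``.

    Returns +∞ exactly when ρ is +∞ (inadmissible block).
    """
    rho_val = rho(pen.reg, r, s)
    if math.isinf(rho_val):
        return math.inf
    return prefix.nll(r, s) + pen.weight(n) * rho_val


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SegmentationResult:
    """A fitted segmentation: change-points, per-block MLEs, and PL value."""

    change_points: ChangePointSet
    block_params: tuple
    total_nll: float
    total_penalty: float
    family: str
    n: int
    lam: float
    sample_penalty: str
    j_value: float

    @property
    def pl_value(self) -> float:
        return self.total_nll + self.total_penalty

    @property
    def m(self) -> int:
        return self.change_points.m

    @property
    def k(self) -> int:
        """Number of interior change-points detected."""
        return self.change_points.n_change_points

    def to_dict(self, positions=None, chrom=None) -> dict:
        blocks = []
        for (r, s), est in zip(self.change_points.blocks(), self.block_params):
            entry = {"start_col": r, "end_col": s, "nll": est.nll,
                     "n_obs": est.n_obs, **est.theta}
            if positions is not None:
                entry["start_bp"] = int(positions[r - 1])
                entry["end_bp"] = int(positions[s - 1])
            blocks.append(entry)
        doc = {
            "family": self.family,
            "n": self.n,
            "m": self.m,
            "lambda": self.lam,
            "sample_penalty": self.sample_penalty,
            "j_value": self.j_value,
            "change_points": list(self.change_points.points),
            "k": self.k,
            "total_nll": self.total_nll,
            "total_penalty": self.total_penalty,
            "pl_value": self.pl_value,
            "blocks": blocks,
        }
        if chrom is not None:
            doc["chrom"] = chrom
        return doc

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(**kw), indent=2)


_NON_THETA_KEYS = {"start_col", "end_col", "nll", "n_obs", "start_bp", "end_bp"}


def segmentation_result_from_dict(doc: dict) -> SegmentationResult:
    """Rebuild a :class:`SegmentationResult` from its serialized document."""
    fits = tuple(
        BlockEstimate(
            theta={k: v for k, v in entry.items() if k not in _NON_THETA_KEYS},
            nll=float(entry["nll"]),
            n_obs=int(entry["n_obs"]),
        )
        for entry in doc["blocks"]
    )
    return SegmentationResult(
        change_points=ChangePointSet(tuple(doc["change_points"])),
        block_params=fits,
        total_nll=float(doc["total_nll"]),
        total_penalty=float(doc["total_penalty"]),
        family=doc["family"],
        n=int(doc["n"]),
        lam=float(doc["lambda"]),
        sample_penalty=doc["sample_penalty"],
        j_value=float(doc["j_value"]),
    )


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------
def _assemble(
    prefix: SufficientStatPrefix, pen: PenaltySpec, n: int, points
) -> SegmentationResult:
    cps = points if isinstance(points, ChangePointSet) else ChangePointSet(tuple(points))
    fits = []
    total_nll = 0.0
    total_rho = 0.0
    for r, s in cps.blocks():
        est = prefix.fit(r, s)
        fits.append(est)
        total_nll += est.nll
        total_rho += rho(pen.reg, r, s)
    j = pen.J(n)
    # an inadmissible block makes the whole segmentation infinite-cost,
    # even at lambda = 0
    penalty = math.inf if math.isinf(total_rho) else pen.lam * j * total_rho
    return SegmentationResult(
        change_points=cps,
        block_params=tuple(fits),
        total_nll=total_nll,
        total_penalty=penalty,
        family=prefix.family,
        n=n,
        lam=pen.lam,
        sample_penalty=pen.sample_penalty_label,
        j_value=j,
    )


def _penalized(nll: np.ndarray, rho_vec: np.ndarray, w: float) -> np.ndarray:
    """Q = nll + w·ρ, with +∞ wherever ρ is +∞ (even at w = 0)."""
    return np.where(np.isinf(rho_vec), np.inf, nll + w * rho_vec)


def _solve_dp(prefix: SufficientStatPrefix, pen: PenaltySpec, n: int) -> tuple:
    """Exact optimal-partitioning recursion; returns the change-point tuple.

    F(0) = 0; F(i) = min over previous boundaries c < i of
    F(c) + Q((c+1):i).  ``np.argmin`` returns the first minimizer, which
    realizes the leftmost tie-break.
    """
    m = prefix.m
    w = pen.weight(n)
    const_reg = isinstance(pen.reg, ConstantPerBlock)
    F = np.empty(m + 1)
    F[0] = 0.0
    back = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, m + 1):
        q = prefix.nll_starts(i)
        if const_reg:
            q = q + w
        else:
            q = _penalized(q, pen.reg.rho_starts(i), w)
        cand = F[:i] + q
        j = int(np.argmin(cand))
        F[i] = cand[j]
        back[i] = j
    if not np.isfinite(F[m]):
        raise ComputationError(
            "no finite-cost segmentation exists: every admissible partition "
            "contains a block with infinite regularizer (check the span "
            "threshold T against the marker positions)"
        )
    pts = [m]
    i = m
    while i > 0:
        i = int(back[i])
        pts.append(i)
    return tuple(reversed(pts))


def _solve_hierarchical(
    prefix: SufficientStatPrefix, pen: PenaltySpec, n: int
) -> tuple:
    """Greedy binary segmentation; returns the change-point tuple.

    For the current interval I = r:s the candidate scores are
    h_I(c) = PL(r:c) + PL((c+1):s) for c in r..s, where PL of an interval
    is its unsplit penalized cost and PL(∅) = 0 (so h_I(s) = PL(I)).
    The interval is split at the leftmost minimizer iff the score strictly
    improves PL(I); both halves are then processed recursively.
    """
    m = prefix.m
    w = pen.weight(n)
    const_reg = isinstance(pen.reg, ConstantPerBlock)
    if math.isinf(rho(pen.reg, 1, m)):
        raise ComputationError(
            "the whole-interval block already has infinite regularizer, so "
            "every sub-block does too; no admissible segmentation exists "
            "(span threshold T is at least the full marker span)"
        )
    interior: list = []
    stack = [(1, m)]
    while stack:
        r, s = stack.pop()
        if r == s:
            continue
        # PL(r:c) for c = r..s
        left = prefix.nll_ends(r)[: s - r + 1]
        if const_reg:
            left = left + w
        else:
            left = _penalized(left, pen.reg.rho_ends(r, s), w)
        # PL((c+1):s) for c = r..s−1, plus PL(∅)=0 at c=s
        starts = prefix.nll_starts(s)
        if const_reg:
            starts = starts + w
        else:
            starts = _penalized(starts, pen.reg.rho_starts(s), w)
        right = np.concatenate((starts[r : s], [0.0]))
        h = left + right
        pl_interval = h[-1]  # h_I(s) = PL(I)
        j = int(np.argmin(h))
        c = r + j
        if c < s and h[j] < pl_interval:
            interior.append(c)
            stack.append((r, c))
            stack.append((c + 1, s))
    return (0, *sorted(interior), m)


def fit_dp(
    data: DataMatrix, pen: PenaltySpec, *, variance_floor: float = 1e-8
) -> SegmentationResult:
    """Exact penalized-likelihood segmentation by dynamic programming.

    Globally minimizes PL over all change-point sets; on ties the
    segmentation reached by leftmost previous-boundary choices is
    returned, making the output deterministic.
    """
    prefix = build_prefix(data, variance_floor=variance_floor)
    return _assemble(prefix, pen, data.n, _solve_dp(prefix, pen, data.n))


def fit_hierarchical(
    data: DataMatrix, pen: PenaltySpec, *, variance_floor: float = 1e-8
) -> SegmentationResult:
    """Greedy binary-segmentation approximation to :func:`fit_dp`.

    Much faster on long sequences (typically O(m·k) cost queries) and, on
    well-separated blocks, returns the same segmentation as the exact
    solver; its PL value is never smaller than the DP optimum.
    """
    prefix = build_prefix(data, variance_floor=variance_floor)
    return _assemble(prefix, pen, data.n, _solve_hierarchical(prefix, pen, data.n))


def pl_of(
    data: DataMatrix,
    pen: PenaltySpec,
    C: ChangePointSet | Sequence[int],
    *,
    variance_floor: float = 1e-8,
) -> SegmentationResult:
    """Evaluate PL and the per-block fits for a user-supplied change-point set."""
    cps = C if isinstance(C, ChangePointSet) else ChangePointSet(tuple(C))
    if cps.m != data.m:
        raise ValidationError(
            f"change-point set ends at {cps.m} but the data has m={data.m} columns"
        )
    prefix = build_prefix(data, variance_floor=variance_floor)
    return _assemble(prefix, pen, data.n, cps)


_SOLVERS = {
    "dp": _solve_dp,
    "hierarchical": _solve_hierarchical,
    "hs": _solve_hierarchical,
}
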