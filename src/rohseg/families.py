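"""Model families as sufficient-statistic providers.

Every block cost in the segmentation objective is a maximized negative
log-likelihood of one column interval.  Evaluating it naively touches
``n × blocklen`` entries; instead we cumulate each family's sufficient
statistics over columns once (cost proportional to ``n·m``) and answer any
interval query from prefix differences in O(1).

Column intervals are 1-based and inclusive throughout: the block between
consecutive change-points ``c_{j-1} < c_j`` is ``(c_{j-1}+1):c_j``.

Families
--------
bernoulli
    Sufficient statistics: count of ones ``S`` and count of observed
    entries ``N`` per block.  MLE ``p̂ = S/N``; block negative
    log-likelihood ``−[S·log p̂ + (N−S)·log(1−p̂)]`` with ``0·log 0 = 0``.
gaussian (unknown mean and variance)
    Sufficient statistics: sum, sum of squares, observed count.  MLEs
    ``μ̂ = S₁/N``, ``σ̂² = S₂/N − μ̂²`` (clamped below by a configurable
    floor); block nll ``(N/2)·(log(2π σ̂²) + 1)``.

Missing entries are excluded via the mask; the likelihood runs over
observed entries only, consistent with the per-entry i.i.d. product form
of the block model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .data import DataMatrix
from .errors import ValidationError

__all__ = ["BlockEstimate", "SufficientStatPrefix", "build_prefix", "block_fit"]


@dataclass(frozen=True)
class BlockEstimate:
    """Fitted parameters and negative log-likelihood of one block.

    ``theta`` maps parameter names to MLE values (``{"p": ...}`` for
    bernoulli, ``{"mean": ..., "var": ...}`` for gaussian); ``nll`` is the
    block's −log-likelihood at the MLE, summed over observed entries.
    """

    theta: dict
    nll: float
    n_obs: int


class SufficientStatPrefix:
    """Per-column cumulative sufficient statistics (length m+1, index 0 zero).

    Subclasses implement the family-specific closed forms.  The vectorized
    queries ``nll_starts``/``nll_ends`` return the nll of every block
    sharing an endpoint and are what make the dynamic program O(m²) overall.
    """

    family: str

    def __init__(self, data: DataMatrix):
        self.n_rows = data.n
        self._m = data.m
        counts = data.mask.sum(axis=0).astype(np.float64)
        self.count = np.concatenate(([0.0], np.cumsum(counts)))

    @property
    def m(self) -> int:
        return self._m

    def _check_interval(self, r: int, s: int) -> None:
        if not (1 <= r <= s <= self.m):
            raise ValidationError(
                f"invalid block interval {r}:{s} (need 1 <= r <= s <= m={self.m})"
            )

    # -- scalar queries -------------------------------------------------
    def nll(self, r: int, s: int) -> float:
        """Negative log-likelihood of block ``r:s`` at the block MLE."""
        self._check_interval(r, s)
        return float(self.nll_starts(s)[r - 1])

    def fit(self, r: int, s: int) -> BlockEstimate:
        raise NotImplementedError

    # -- vectorized queries ---------------------------------------------
    def nll_starts(self, s: int) -> np.ndarray:
        """nll of blocks ``r:s`` for all r = 1..s (index r−1)."""
        raise NotImplementedError

    def nll_ends(self, r: int) -> np.ndarray:
        """nll of blocks ``r:s`` for all s = r..m (index s−r)."""
        raise NotImplementedError


class BernoulliPrefix(SufficientStatPrefix):
    family = "bernoulli"

    def __init__(self, data: DataMatrix):
        if data.family != "bernoulli":
            raise ValidationError(f"data family is {data.family!r}, not bernoulli")
        super().__init__(data)
        ones = np.where(data.mask, data.values, 0.0).sum(axis=0)
        self.ones = np.concatenate(([0.0], np.cumsum(ones)))

    @staticmethod
    def _nll_from_totals(S, N):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = S / N
            nll = -(xlogy(S, p) + xlogy(N - S, 1.0 - p))
        return np.where(N > 0, nll, 0.0)

    def nll_starts(self, s: int) -> np.ndarray:
        S = self.ones[s] - self.ones[:s]
        N = self.count[s] - self.count[:s]
        return self._nll_from_totals(S, N)

    def nll_ends(self, r: int) -> np.ndarray:
        S = self.ones[r:] - self.ones[r - 1]
        N = self.count[r:] - self.count[r - 1]
        return self._nll_from_totals(S, N)

    def fit(self, r: int, s: int) -> BlockEstimate:
        self._check_interval(r, s)
        S = self.ones[s] - self.ones[r - 1]
        N = self.count[s] - self.count[r - 1]
        if N == 0:
            raise ValidationError(f"block {r}:{s} has no observed entries")
        p = S / N
        nll = -(xlogy(S, p) + xlogy(N - S, 1.0 - p))
        return BlockEstimate(theta={"p": float(p)}, nll=float(nll), n_obs=int(N))


class GaussianPrefix(SufficientStatPrefix):
    family = "gaussian"

    def __init__(self, data: DataMatrix, variance_floor: float = 1e-8):
        if data.family != "gaussian":
            raise ValidationError(f"data family is {data.family!r}, not gaussian")
        if variance_floor <= 0:
            raise ValidationError("variance_floor must be positive")
        super().__init__(data)
        self.variance_floor = float(variance_floor)
        obs = np.where(data.mask, data.values, 0.0)
        self.sum1 = np.concatenate(([0.0], np.cumsum(obs.sum(axis=0))))
        self.sum2 = np.concatenate(([0.0], np.cumsum((obs * obs).sum(axis=0))))

    def _nll_from_totals(self, S1, S2, N):
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = S1 / N
            var = np.maximum(S2 / N - mu * mu, self.variance_floor)
            nll = 0.5 * N * (np.log(2.0 * np.pi * var) + 1.0)
        return np.where(N > 0, nll, 0.0)

    def nll_starts(self, s: int) -> np.ndarray:
        sl = slice(None, s)
        return self._nll_from_totals(
            self.sum1[s] - self.sum1[sl],
            self.sum2[s] - self.sum2[sl],
            self.count[s] - self.count[sl],
        )

    def nll_ends(self, r: int) -> np.ndarray:
        return self._nll_from_totals(
            self.sum1[r:] - self.sum1[r - 1],
            self.sum2[r:] - self.sum2[r - 1],
            self.count[r:] - self.count[r - 1],
        )

    def fit(self, r: int, s: int) -> BlockEstimate:
        self._check_interval(r, s)
        N = self.count[s] - self.count[r - 1]
        if N == 0:
            raise ValidationError(f"block {r}:{s} has no observed entries")
        mu = (self.sum1[s] - self.sum1[r - 1]) / N
        var = max((self.sum2[s] - self.sum2[r - 1]) / N - mu * mu, self.variance_floor)
        nll = 0.5 * N * (np.log(2.0 * np.pi * var) + 1.0)
        return BlockEstimate(
            theta={"mean": float(mu), "var": float(var)},
            nll=float(nll),
            n_obs=int(N),
        )


def build_prefix(
    data: DataMatrix, variance_floor: float = 1e-8
) -> SufficientStatPrefix:
    """Cumulate the family's sufficient statistics over columns.

    Returns a prefix object answering any block query in O(1):
    block totals over ``r:s`` are ``prefix[s] − prefix[r−1]``.
    """
    if data.family == "bernoulli":
        return BernoulliPrefix(data)
    return GaussianPrefix(data, variance_floor=variance_floor)


def block_fit(prefix: SufficientStatPrefix, r: int, s: int) -> BlockEstimate:
    """MLE and negative log-likelihood of block ``r:s`` (1-based inclusive)."""
    return prefix.fit(r, s)
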