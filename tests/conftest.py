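"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's prefix-sum fast paths:
block likelihoods are recomputed entry by entry, and optimal
segmentations by exhaustive enumeration over all 2^(m-1) change-point
sets, so that agreement with the library is a genuine cross-check.
"""

import itertools

import numpy as np
import pytest

from rohseg import ChangePointSet, DataMatrix, PenaltySpec, pl_of


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_bernoulli(rng, n, m, missing=0.0):
    values = (rng.random((n, m)) < rng.uniform(0.1, 0.9, size=m)).astype(float)
    mask = rng.random((n, m)) >= missing
    # keep at least one observed entry per column
    for j in range(m):
        if not mask[:, j].any():
            mask[rng.integers(n), j] = True
    return DataMatrix(values=values, family="bernoulli", mask=mask)


def random_gaussian(rng, n, m, missing=0.0):
    values = rng.normal(rng.normal(0, 2, size=m), 1.0, size=(n, m))
    mask = rng.random((n, m)) >= missing
    for j in range(m):
        if not mask[:, j].any():
            mask[rng.integers(n), j] = True
    return DataMatrix(values=values, family="gaussian", mask=mask)


def per_entry_nll(data: DataMatrix, r: int, s: int, variance_floor=1e-8):
    """Brute-force -sum log f_theta_hat over the raw entries of block r:s."""
    block = data.values[:, r - 1 : s]
    mask = data.mask[:, r - 1 : s]
    obs = block[mask]
    if data.family == "bernoulli":
        p = obs.mean()
        total = 0.0
        for x in obs:
            if x == 1.0:
                total += 0.0 if p == 1.0 else -np.log(p)
            else:
                total += 0.0 if p == 0.0 else -np.log(1.0 - p)
        return total
    mu = obs.mean()
    var = max(obs.var(), variance_floor)
    return float(
        sum(
            0.5 * np.log(2 * np.pi * var) + 0.5 * (x - mu) ** 2 / var
            for x in obs
        )
    )


def all_segmentations(m):
    """Every change-point set over 1:m, as ChangePointSet objects."""
    for k in range(m):
        for interior in itertools.combinations(range(1, m), k):
            yield ChangePointSet((0, *interior, m))


def exhaustive_minimum(data: DataMatrix, pen: PenaltySpec):
    """(best PL, list of minimizing sets) by enumeration over all of C."""
    best = np.inf
    argmins = []
    for cps in all_segmentations(data.m):
        val = pl_of(data, pen, cps).pl_value
        if val < best - 1e-9:
            best, argmins = val, [cps]
        elif abs(val - best) <= 1e-9:
            argmins.append(cps)
    return best, argmins
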