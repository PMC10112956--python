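"""Penalized-likelihood objective, regularizers, and both solvers."""

import math

import numpy as np
import pytest

from rohseg import (
    ChangePointSet,
    ComputationError,
    ConstantPerBlock,
    DataMatrix,
    PenaltySpec,
    RohRegularization,
    SimulationScenario,
    ValidationError,
    block_cost,
    build_prefix,
    fit_dp,
    fit_hierarchical,
    pl_of,
    rho,
    simulate,
)
from rohseg.segmentation import segmentation_result_from_dict

from conftest import exhaustive_minimum, random_bernoulli, random_gaussian


def two_level_bernoulli(n=200, m=10, split=5, p=(0.05, 0.95), seed=5):
    scenario = SimulationScenario(
        "bernoulli", ChangePointSet((0, split, m)), p
    )
    return simulate(scenario, n, seed=seed), scenario


class TestChangePointSet:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ChangePointSet((1, 5))
        with pytest.raises(ValidationError):
            ChangePointSet((0, 5, 5, 10))
        with pytest.raises(ValidationError):
            ChangePointSet((0,))

    def test_counts(self):
        c = ChangePointSet((0, 3, 7, 10))
        assert c.n_blocks == 3
        assert c.n_change_points == 2
        assert list(c.blocks()) == [(1, 3), (4, 7), (8, 10)]


class TestRho:
    def test_constant_reg_is_one(self):
        assert rho(ConstantPerBlock(), 3, 17) == 1.0

    def test_sub_threshold_span_is_infinite(self):
        reg = RohRegularization([1_000_000, 1_500_000], threshold_mb=1.0)
        assert rho(reg, 1, 2) == math.inf

    def test_supra_threshold_reciprocal_megabase_span(self):
        # 5 Mb span above the 1 Mb threshold: rho = 1 / 5 Mb
        reg = RohRegularization([0, 5_000_000], threshold_mb=1.0)
        assert rho(reg, 1, 2) == pytest.approx(0.2)

    def test_splitting_increases_regularization(self):
        reg = RohRegularization([0, 2_000_000, 5_000_000], threshold_mb=1.0)
        assert rho(reg, 1, 3) < rho(reg, 1, 2) + rho(reg, 2, 3)

    def test_positions_required_and_increasing(self):
        with pytest.raises(ValidationError):
            RohRegularization([], threshold_mb=1.0)
        with pytest.raises(ValidationError):
            RohRegularization([5, 3], threshold_mb=1.0)


class TestBlockCost:
    def test_zero_lambda_equals_nll(self, rng):
        data = random_bernoulli(rng, 10, 6)
        pre = build_prefix(data)
        pen = PenaltySpec(lam=0.0)
        assert block_cost(pre, pen, 10, 2, 5) == pytest.approx(pre.nll(2, 5))

    def test_infinite_rho_propagates(self, rng):
        data = random_bernoulli(rng, 10, 2)
        pre = build_prefix(data)
        pen = PenaltySpec(
            lam=1.0, reg=RohRegularization([100, 200], threshold_mb=1.0)
        )
        assert block_cost(pre, pen, 10, 1, 2) == math.inf

    def test_penalty_arithmetic(self, rng):
        # nll + lambda * J(n) * rho = nll + 2 * sqrt(100) * 1
        data = random_bernoulli(rng, 10, 4)
        pre = build_prefix(data)
        pen = PenaltySpec(lam=2.0, sample_penalty="sqrt_n")
        expected = pre.nll(1, 4) + 2.0 * 10.0 * 1.0
        assert block_cost(pre, pen, 100, 1, 4) == pytest.approx(expected)


class TestDP:
    def test_constant_data_returns_single_block(self):
        data = DataMatrix(np.zeros((100, 50)), "bernoulli")
        res = fit_dp(data, PenaltySpec(lam=1.0))
        assert res.change_points.points == (0, 50)
        assert res.block_params[0].theta["p"] == 0.0

    def test_matches_bruteforce_on_two_level_signal(self):
        data, scenario = two_level_bernoulli()
        pen = PenaltySpec(lam=1.0)
        res = fit_dp(data, pen)
        best, argmins = exhaustive_minimum(data, pen)
        assert res.pl_value == pytest.approx(best, rel=1e-9)
        assert res.change_points.points in [c.points for c in argmins]
        assert res.change_points.points == (0, 5, 10)

    def test_huge_lambda_collapses_to_single_block(self, rng):
        data = random_bernoulli(rng, 30, 12)
        res = fit_dp(data, PenaltySpec(lam=1e9))
        assert res.change_points.points == (0, 12)

    @pytest.mark.parametrize("family", ["bernoulli", "gaussian"])
    def test_matches_exhaustive_on_random_data(self, rng, family):
        make = random_bernoulli if family == "bernoulli" else random_gaussian
        for seed_off in range(5):
            data = make(rng, 25, 8)
            pen = PenaltySpec(lam=0.5 + 0.5 * seed_off)
            res = fit_dp(data, pen)
            best, argmins = exhaustive_minimum(data, pen)
            assert res.pl_value == pytest.approx(best, rel=1e-9)
            assert res.change_points.points in [c.points for c in argmins]

    def test_k_monotone_in_lambda(self, rng):
        data = random_bernoulli(rng, 60, 25)
        ks = [
            fit_dp(data, PenaltySpec(lam=lam)).k
            for lam in (0.05, 0.2, 0.5, 1.0, 2.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_deterministic(self, rng):
        data = random_gaussian(rng, 40, 15)
        pen = PenaltySpec(lam=0.7)
        assert (
            fit_dp(data, pen).change_points.points
            == fit_dp(data, pen).change_points.points
        )


class TestHierarchical:
    def test_agrees_with_dp_on_strong_single_change(self):
        data, _ = two_level_bernoulli()
        pen = PenaltySpec(lam=1.0)
        assert (
            fit_hierarchical(data, pen).change_points.points
            == fit_dp(data, pen).change_points.points
        )

    def test_constant_data_never_splits(self):
        data = DataMatrix(np.zeros((50, 30)), "bernoulli")
        res = fit_hierarchical(data, PenaltySpec(lam=0.5))
        assert res.change_points.points == (0, 30)

    @pytest.mark.parametrize("family", ["bernoulli", "gaussian"])
    def test_never_beats_dp(self, rng, family):
        make = random_bernoulli if family == "bernoulli" else random_gaussian
        for _ in range(25):
            n = int(rng.integers(15, 50))
            m = int(rng.integers(8, 30))
            data = make(rng, n, m)
            pen = PenaltySpec(lam=float(rng.uniform(0.1, 2.0)))
            assert (
                fit_dp(data, pen).pl_value
                <= fit_hierarchical(data, pen).pl_value + 1e-9
            )


class TestPLof:
    def test_single_block_matches_whole_fit(self, rng):
        data = random_gaussian(rng, 20, 8)
        pen = PenaltySpec(lam=1.0)
        res = pl_of(data, pen, ChangePointSet((0, 8)))
        pre = build_prefix(data)
        assert res.total_nll == pytest.approx(pre.nll(1, 8), rel=1e-12)
        assert res.pl_value == pytest.approx(
            pre.nll(1, 8) + pen.weight(20), rel=1e-12
        )

    def test_dp_not_beaten_by_random_sets(self, rng):
        data = random_bernoulli(rng, 30, 10)
        pen = PenaltySpec(lam=0.8)
        opt = fit_dp(data, pen).pl_value
        for _ in range(1000):
            k = int(rng.integers(0, 9))
            interior = sorted(
                rng.choice(np.arange(1, 10), size=k, replace=False).tolist()
            )
            val = pl_of(data, pen, ChangePointSet((0, *interior, 10))).pl_value
            assert opt <= val + 1e-9

    def test_refinement_monotone_at_zero_lambda(self, rng):
        data = random_gaussian(rng, 15, 10)
        pen = PenaltySpec(lam=0.0)
        coarse = pl_of(data, pen, ChangePointSet((0, 5, 10))).pl_value
        fine = pl_of(data, pen, ChangePointSet((0, 3, 5, 8, 10))).pl_value
        assert fine <= coarse + 1e-9

    def test_pl_value_consistency(self, rng):
        data = random_bernoulli(rng, 20, 9)
        res = pl_of(data, PenaltySpec(lam=1.3), ChangePointSet((0, 4, 9)))
        assert res.pl_value == pytest.approx(
            res.total_nll + res.total_penalty, abs=1e-9
        )

    def test_wrong_m_rejected(self, rng):
        data = random_bernoulli(rng, 5, 6)
        with pytest.raises(ValidationError):
            pl_of(data, PenaltySpec(lam=1.0), ChangePointSet((0, 3, 7)))


class TestRohConstraint:
    def _random_map(self, rng, m, spacing_bp=200_000):
        gaps = rng.integers(50_000, spacing_bp, size=m)
        return np.cumsum(gaps) + 1

    @pytest.mark.parametrize("solver", [fit_dp, fit_hierarchical])
    def test_no_block_at_or_below_threshold(self, rng, solver):
        for _ in range(10):
            m = 30
            positions = self._random_map(rng, m)
            t_mb = float(rng.uniform(0.3, 1.0))
            data = random_bernoulli(rng, 40, m)
            pen = PenaltySpec(
                lam=0.5, reg=RohRegularization(positions, threshold_mb=t_mb)
            )
            res = solver(data, pen)
            for r, s in res.change_points.blocks():
                span_mb = (positions[s - 1] - positions[r - 1]) / 1e6
                assert span_mb > t_mb

    def test_impossible_threshold_raises(self, rng):
        data = random_bernoulli(rng, 10, 5)
        reg = RohRegularization([100, 200, 300, 400, 500], threshold_mb=10.0)
        pen = PenaltySpec(lam=0.5, reg=reg)
        with pytest.raises(ComputationError):
            fit_dp(data, pen)
        with pytest.raises(ComputationError):
            fit_hierarchical(data, pen)


def test_result_serialization_round_trip(rng):
    data = random_gaussian(rng, 25, 12)
    res = fit_dp(data, PenaltySpec(lam=0.6))
    doc = res.to_dict()
    back = segmentation_result_from_dict(doc)
    assert back == res


def test_sample_penalty_variants():
    pen_sqrt = PenaltySpec(lam=2.0, sample_penalty="sqrt_n")
    pen_log = PenaltySpec(lam=2.0, sample_penalty="log_n")
    pen_custom = PenaltySpec(lam=2.0, sample_penalty=lambda n: n**0.25)
    assert pen_sqrt.J(100) == pytest.approx(10.0)
    assert pen_log.J(math.e**2) == pytest.approx(2.0)
    assert pen_custom.J(16) == pytest.approx(2.0)
    with pytest.raises(ValidationError):
        PenaltySpec(lam=1.0, sample_penalty="bogus")
    with pytest.raises(ValidationError):
        PenaltySpec(lam=-1.0)
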