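"""Concentration index, curve oracle, decomposition and HI.

The covariance form and the curve-area form of the concentration index
are independent routes to the same quantity; the decomposition must
satisfy the adding-up identity exactly because the residual is defined
as the remainder."""

import numpy as np
import pandas as pd
import pytest

from hiequity import (
    RankVector,
    estimate_hi,
    generate,
    null_socioeconomic,
    preset_charls_like,
    weighted_fractional_rank,
)
from hiequity.data_model import DesignMatrix
from hiequity.inequity import (
    ci_from_curve,
    concentration_index,
    decompose,
    horizontal_inequity,
)
from hiequity.synthetic import ground_truth_hi


def _ranks(n):
    return weighted_fractional_rank(np.arange(n, dtype=float))


class TestConcentrationIndex:
    def test_constant_outcome_has_zero_index(self):
        res = concentration_index(np.full(10, 3.0), _ranks(10))
        assert res.index == pytest.approx(0.0, abs=1e-15)

    def test_four_point_hand_computation(self):
        """y=(0,0,1,1) by rising income: mu=1/2, cov=1/8, C=1/2."""
        res = concentration_index(np.array([0.0, 0.0, 1.0, 1.0]), _ranks(4))
        assert res.index == pytest.approx(0.5, abs=1e-15)
        assert res.mean == 0.5
        # same value from the curve-area oracle (exact for this step curve)
        assert ci_from_curve(res.curve) == pytest.approx(0.5, abs=1e-12)

    def test_outcome_scaling_invariance(self, rng):
        y = rng.random(50)
        r = _ranks(50)
        c1 = concentration_index(y, r).index
        c2 = concentration_index(17.3 * y, r).index
        assert c1 == pytest.approx(c2, abs=1e-14)

    def test_all_zero_outcome_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            concentration_index(np.zeros(5), _ranks(5))

    def test_equal_weights_match_unweighted_exactly(self, rng):
        y = rng.random(80)
        r = _ranks(80)
        c_u = concentration_index(y, r).index
        c_w = concentration_index(y, r, np.full(80, 3.7)).index
        assert c_u == c_w

    def test_rank_reversal_flips_sign(self, rng):
        y = rng.random(60)
        w = rng.uniform(0.5, 2.0, 60)
        r = weighted_fractional_rank(rng.random(60), w)
        c = concentration_index(y, r, w).index
        c_rev = concentration_index(y, RankVector(1.0 - r.rank), w).index
        assert c_rev == pytest.approx(-c, abs=1e-14)

    def test_bounded_for_binary_outcomes(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 300))
            y = (rng.random(n) < rng.uniform(0.05, 0.95)).astype(float)
            if y.sum() == 0:
                continue
            c = concentration_index(y, _ranks(n)).index
            mu = y.mean()
            assert abs(c) <= 1.0
            assert abs(c) <= 1.0 - mu + 1.0 / n + 1e-12

    def test_covariance_and_curve_routes_agree(self, rng):
        """Eq.-style covariance CI vs twice-the-area CI within 2/n on
        1000 randomized instances."""
        for _ in range(1000):
            n = int(rng.integers(10, 1001))
            y = rng.choice([0.0, 1.0], size=n, p=[0.8, 0.2]) if rng.random() < 0.5 \
                else rng.random(n)
            if not y.any():
                y[0] = 1.0
            w = rng.uniform(0.2, 3.0, n) if rng.random() < 0.5 else None
            r = weighted_fractional_rank(rng.random(n), w)
            res = concentration_index(y, r, w)
            assert abs(res.index - ci_from_curve(res.curve)) <= 2.0 / n


class TestCurve:
    def test_diagonal_curve_gives_zero(self):
        t = np.linspace(0, 1, 11)
        assert ci_from_curve(np.column_stack([t, t])) == pytest.approx(0.0, abs=1e-15)

    def test_curve_above_diagonal_is_negative(self):
        t = np.linspace(0, 1, 101)
        assert ci_from_curve(np.column_stack([t, np.sqrt(t)])) < 0

    def test_curve_endpoints_and_monotonicity(self, rng):
        y = rng.random(40)
        res = concentration_index(y, _ranks(40))
        assert res.curve[0].tolist() == [0.0, 0.0]
        assert np.allclose(res.curve[-1], [1.0, 1.0])
        assert (np.diff(res.curve[:, 0]) >= 0).all()
        assert (np.diff(res.curve[:, 1]) >= -1e-12).all()

    def test_unsorted_curve_rejected(self):
        with pytest.raises(ValueError):
            ci_from_curve(np.array([[0.0, 0.0], [0.7, 0.5], [0.3, 0.2], [1.0, 1.0]]))


def _toy_design():
    data = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
    return DesignMatrix(data=data, roles={"x": "socioeconomic"},
                        groups={"x": "x"}, reference_categories={})


class TestDecomposition:
    def test_single_covariate_hand_arithmetic(self):
        """AME 0.2, xbar/ybar = 1, C_x = 0.25 -> contribution 0.05."""
        y = np.array([0.0, 0.0, 1.0, 1.0])
        res = decompose(pd.Series({"x": 0.2}), _toy_design(), y, _ranks(4))
        assert res.table.loc["x", "ci_x"] == pytest.approx(0.25, abs=1e-15)
        assert res.table.loc["x", "contribution"] == pytest.approx(0.05, abs=1e-15)
        assert res.residual == pytest.approx(res.total_index - 0.05, abs=1e-15)

    def test_adding_up_identity_is_exact(self, preset_dataset):
        _, records, _ = preset_dataset
        for scheme in ("URRBMI", "NCMS"):
            sub = records[records.scheme == scheme]
            for outcome in ("outpatient", "inpatient"):
                d = estimate_hi(sub, outcome)
                assert d.need_total + d.socioeconomic_total + d.residual == pytest.approx(
                    d.total_index, abs=1e-10
                )
                assert d.hi == pytest.approx(d.total_index - d.need_total, abs=1e-12)

    def test_percentages_sum_to_explained_share(self, preset_dataset):
        _, records, _ = preset_dataset
        d = estimate_hi(records[records.scheme == "NCMS"], "outpatient")
        expected = 100.0 * (1.0 - d.residual / d.total_index)
        assert d.table["percent"].sum() == pytest.approx(expected, abs=1e-8)

    def test_missing_ame_rejected(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="x"):
            decompose(pd.Series({"other": 0.1}), _toy_design(), y, _ranks(4))

    def test_zero_mean_outcome_rejected(self):
        with pytest.raises(ValueError):
            decompose(pd.Series({"x": 0.1}), _toy_design(), np.zeros(4), _ranks(4))


class TestHorizontalInequity:
    @pytest.mark.parametrize(
        "total, need, expected",
        [(0.005, -0.019, 0.024), (-0.012, -0.024, 0.012),
         (-0.083, -0.040, -0.043), (-0.053, -0.025, -0.028)],
    )
    def test_published_summary_arithmetic(self, total, need, expected):
        assert horizontal_inequity(total, need) == pytest.approx(expected, abs=1e-12)

    def test_need_equal_to_total_gives_zero(self):
        assert horizontal_inequity(0.31, 0.31) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            horizontal_inequity(np.nan, 0.0)


class TestSimulationRecovery:
    def test_null_socioeconomic_hi_within_monte_carlo_error(self):
        """With all socioeconomic coefficients zeroed (n = 20,000) the
        estimated HI of both outcomes is within 3 Monte-Carlo SEs of 0."""
        cfg = null_socioeconomic(preset_charls_like(n_total=20000))
        his = {"outpatient": [], "inpatient": []}
        for rep in range(8):
            cfg.seed = 1000 + rep
            rec, _ = generate(cfg)
            for outcome in his:
                his[outcome].append(estimate_hi(rec, outcome).hi)
        for outcome, values in his.items():
            v = np.asarray(values)
            mc_se = v.std(ddof=1)
            assert abs(v[0]) < 3.0 * mc_se, (outcome, v)

    def test_pro_rich_effect_recovered(self):
        """An injected positive top-quintile effect yields positive
        estimated HI and recovers the generator's ground-truth HI
        within Monte-Carlo error (n = 50,000, 20 seeds)."""
        cfg = preset_charls_like(n_total=50000)
        cfg.outcome_coefficients["outpatient"]["income_q5"] = 0.5
        est, true = [], []
        for rep in range(20):
            cfg.seed = 3000 + rep
            rec, truth = generate(cfg)
            est.append(estimate_hi(rec, "outpatient").hi)
            true.append(ground_truth_hi(cfg, truth, rec, "outpatient"))
        est, true = np.asarray(est), np.asarray(true)
        assert (est > 0).all()
        diff = est - true
        assert abs(diff.mean()) <= 3.0 * diff.std(ddof=1) / np.sqrt(len(diff))
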