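"""Weighted logit fit, zero-event level handling, and average marginal
effects, checked against closed-form saturated-model MLEs and a
finite-difference oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from hiequity import encode_design, generate, preset_charls_like
from hiequity.outcome_model import (
    LogitFit,
    average_marginal_effects,
    drop_zero_event_categories,
    fit_logit,
)


def _two_by_two():
    """200 rows: 30/100 events at x=1, 10/100 at x=0 (saturated 2x2)."""
    x = np.repeat([1.0, 0.0], 100)
    y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
    return y, pd.DataFrame({"x": x})


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = fit_logit(y, pd.DataFrame(index=range(100)))
        assert fit.params["const"] == pytest.approx(np.log(1 / 3), abs=1e-4)

    def test_saturated_two_by_two_equals_log_odds_ratio(self):
        y, X = _two_by_two()
        fit = fit_logit(y, X)
        assert fit.params["x"] == pytest.approx(np.log((30 * 90) / (70 * 10)), abs=1e-4)

    def test_weight_rescaling_leaves_coefficients_unchanged(self, rng):
        y, X = _two_by_two()
        w = rng.uniform(0.5, 2.0, size=len(y))
        f1 = fit_logit(y, X, w)
        f2 = fit_logit(y, X, 7.0 * w)
        pd.testing.assert_series_equal(f1.params, f2.params, atol=1e-10, rtol=0)

    def test_score_vanishes_at_optimum(self, preset_dataset):
        _, records, _ = preset_dataset
        sub = records[records.scheme == "NCMS"].reset_index(drop=True)
        d = encode_design(sub)
        w = sub.weight.to_numpy()
        fit = fit_logit(sub.outpatient.to_numpy(float), d.data, w)
        Xc = np.column_stack([np.ones(len(sub)), d.data.to_numpy(float)])
        p = fit.predict_proba(d.data)
        score = Xc.T @ (w * (sub.outpatient.to_numpy(float) - p))
        assert np.abs(score).max() < 1e-8

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logit(np.zeros(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_complete_separation_names_column(self):
        x = np.repeat([0.0, 1.0], 20)
        y = x.copy()  # event iff x == 1
        with pytest.raises(Exception, match="x"):
            fit_logit(y, pd.DataFrame({"x": x}))


class TestDropZeroEventCategories:
    def _group(self, n_total, n_excellent, outcome_rate=0.13, seed=0):
        g = np.random.default_rng(seed)
        rec = make_records(
            n_total,
            self_health=[1] * n_excellent + [2 + g.integers(0, 4)
                                             for _ in range(n_total - n_excellent)],
            income=list(g.lognormal(7, 2, n_total)),
            age=list(g.integers(45, 85, n_total)),
        )
        y = (g.random(n_total) < outcome_rate).astype(float)
        y[:n_excellent] = 0.0  # no events in the "excellent" level
        return y, encode_design(rec)

    def test_study_sized_group_shrinks_to_printed_n(self):
        y, d = self._group(3593, 38)
        keep, reduced, log = drop_zero_event_categories(y, d)
        assert keep.sum() == 3555
        assert log == {"self_health_excellent": 38}
        assert "self_health_excellent" not in reduced.columns

    def test_no_zero_event_level_is_identity(self):
        # all incomes in one quintile so no sparsely-populated income dummy;
        # nearly every row is an event so no level can be event-free
        rec = make_records(50, self_health=[1 + i % 5 for i in range(50)],
                           income=[20.0 + i for i in range(50)])
        y = np.ones(50)
        y[7] = 0.0
        d = encode_design(rec)
        keep, reduced, log = drop_zero_event_categories(y, d)
        assert log == {} and keep.all() and reduced is d

    def test_two_zero_event_levels_both_dropped(self):
        rec = make_records(40, self_health=[1] * 5 + [2] * 5 + [3] * 30,
                           education=[0] * 40)
        y = np.zeros(40)
        y[12:20] = 1.0
        keep, reduced, log = drop_zero_event_categories(y, encode_design(rec))
        assert set(log) == {"self_health_excellent", "self_health_very_good"}
        assert keep.sum() == 30


class TestAverageMarginalEffects:
    def test_zero_coefficient_gives_zero_ame(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        fit = LogitFit(
            params=pd.Series({"const": -0.5, "x": 0.0}),
            cov=pd.DataFrame(np.eye(2) * 0.01, index=["const", "x"], columns=["const", "x"]),
            llf=0.0, converged=True, n_iter=1, n_obs=4,
        )
        ame = average_marginal_effects(fit, X)
        assert ame.ame["x"] == 0.0

    def test_saturated_model_recovers_cell_difference(self):
        y, X = _two_by_two()
        fit = fit_logit(y, X)
        ame = average_marginal_effects(fit, X)
        assert ame.ame["x"] == pytest.approx(0.30 - 0.10, abs=1e-8)
        row = ame.table.loc["x"]
        assert row.ci_low < row.ame < row.ci_high

    def test_continuous_ame_matches_finite_difference(self, rng):
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        eta = 0.3 * X["a"] - 0.5 * X["c"] + 0.2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        fit = fit_logit(y, X, w)
        ame = average_marginal_effects(fit, X, w, continuous=set("abcde"))
        h = 1e-6
        for col in X.columns:
            up, dn = X.copy(), X.copy()
            up[col] = up[col] + h
            dn[col] = dn[col] - h
            fd = np.sum(w * (fit.predict_proba(up) - fit.predict_proba(dn))) / (2 * h * w.sum())
            assert ame.ame[col] == pytest.approx(fd, abs=1e-6)

    def test_indicator_ame_bounded_by_one(self, rng):
        for _ in range(20):
            n = 120
            X = pd.DataFrame({
                "a": rng.integers(0, 2, n).astype(float),
                "b": rng.integers(0, 2, n).astype(float),
            })
            eta = rng.normal(0, 2) + rng.normal(0, 2) * X["a"] + rng.normal(0, 2) * X["b"]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.min() == y.max():
                continue
            try:
                fit = fit_logit(y, X)
            except Exception:
                continue
            ame = average_marginal_effects(fit, X)
            assert (ame.ame.abs() <= 1.0).all()

    def test_unknown_column_rejected(self):
        y, X = _two_by_two()
        fit = fit_logit(y, X)
        with pytest.raises(ValueError, match="z"):
            average_marginal_effects(fit, X.assign(z=1.0))


class TestCoverage:
    def test_interval_coverage_on_simulated_data(self):
        """Each logit coefficient's 95% CI covers its true value in >=90%
        of seeded replicates at n = 50,000."""
        from hiequity.outcome_model import Z95

        n_rep = 100
        cfg = preset_charls_like(n_total=50000)
        true = cfg.outcome_coefficients["outpatient"]
        hits = None
        for rep in range(n_rep):
            cfg.seed = 40000 + rep
            rec, truth = generate(cfg)
            d = truth.design
            fit = fit_logit(rec.outpatient.to_numpy(float), d.data,
                            rec.weight.to_numpy())
            se = pd.Series(np.sqrt(np.diag(fit.cov)), index=fit.params.index)
            cover = pd.Series(
                {c: abs(fit.params[c] - true[c]) <= Z95 * se[c] for c in d.columns}
            )
            hits = cover.astype(int) if hits is None else hits + cover.astype(int)
        assert (hits / n_rep >= 0.90).all(), hits[hits / n_rep < 0.90]
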