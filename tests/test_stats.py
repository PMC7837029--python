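"""Correlation maps, random-forest importance, ROC, survival models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from heteroduo.simulate import CohortSimParams, gen_cohort
from heteroduo.stats import (
    PipelineConfig,
    cohort_summary,
    cox_fit,
    km_logrank,
    mann_whitney,
    rf_importance,
    roc_youden,
    run_paper_pipeline,
    spearman_matrix,
)

from .oracles import (
    auc_threshold_oracle,
    cox_loglik_oracle,
    logrank_oracle,
    mann_whitney_p_oracle,
    mann_whitney_u_oracle,
)


class TestSpearman:
    def test_monotone_pairs(self):
        a = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        up = pd.DataFrame({"y": [2.0, 4, 9, 16, 30]})
        down = pd.DataFrame({"y": [30.0, 16, 9, 4, 2]})
        assert spearman_matrix(a, up).rho.loc["x", "y"] == pytest.approx(1.0)
        assert spearman_matrix(a, down).rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_ties_equal_rank_then_pearson(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 30).astype(float)
        got = spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        want = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert got.rho.loc["x", "y"] == pytest.approx(want, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(25)
        y = rng.random(25)
        base = spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        trans = spearman_matrix(
            pd.DataFrame({"x": np.exp(3 * x)}), pd.DataFrame({"y": y**3})
        )
        assert base.rho.loc["x", "y"] == pytest.approx(
            trans.rho.loc["x", "y"], abs=1e-12
        )

    def test_few_pairs_reported_missing(self):
        a = pd.DataFrame({"x": [1.0, 2, np.nan, np.nan, np.nan]})
        b = pd.DataFrame({"y": [1.0, 2, 3, 4, 5]})
        assert np.isnan(spearman_matrix(a, b).rho.loc["x", "y"])


class TestRandomForest:
    def _planted(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(
            rng.standard_normal((n, 10)), columns=[f"f{i}" for i in range(10)]
        )
        y = (x["f0"] > x["f0"].median()).astype(int)
        return x, y

    def test_planted_signal_found(self):
        x, y = self._planted()
        rep = rf_importance(x, y, seed=1)
        assert rep.mean_decrease_accuracy.idxmax() == "f0"
        assert rep.oob_error < 0.15

    def test_null_oob_near_half(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.standard_normal((200, 10)))
        x.columns = [f"f{i}" for i in range(10)]
        y = rng.integers(0, 2, 200)
        rep = rf_importance(x, y, seed=3)
        assert 0.35 <= rep.oob_error <= 0.65

    def test_deterministic(self):
        x, y = self._planted(seed=5)
        a = rf_importance(x, y, seed=9)
        b = rf_importance(x, y, seed=9)
        assert a.oob_error == b.oob_error
        pd.testing.assert_series_equal(
            a.mean_decrease_accuracy, b.mean_decrease_accuracy
        )

    def test_planted_oob_beats_null_oob(self):
        better = 0
        for s in range(20):
            x, y = self._planted(n=120, seed=100 + s)
            planted = rf_importance(x, y, seed=s).oob_error
            y_null = np.random.default_rng(200 + s).permutation(y.to_numpy())
            null = rf_importance(x, y_null, seed=s).oob_error
            better += planted < null
        assert better >= 18

    def test_single_class_rejected(self):
        x, _ = self._planted(n=20)
        with pytest.raises(ValueError):
            rf_importance(x, np.zeros(20, dtype=int))


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        res = mann_whitney(g, g)
        assert res["p"] == pytest.approx(1.0)
        assert mann_whitney_p_oracle(g, g) == pytest.approx(1.0)

    def test_fully_separated_minimal_p(self):
        g0 = np.array([1.0, 2.0, 3.0])
        g1 = np.array([10.0, 11.0, 12.0])
        res = mann_whitney(g0, g1)
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(mann_whitney_p_oracle(g0, g1), abs=1e-12)

    def test_u_statistic_matches_pair_counting(self, rng):
        g0 = rng.integers(0, 6, 12).astype(float)
        g1 = rng.integers(0, 6, 15).astype(float)
        assert mann_whitney(g0, g1)["U"] == pytest.approx(
            mann_whitney_u_oracle(g0, g1)
        )

    def test_single_tied_values(self):
        res = mann_whitney(np.array([5.0]), np.array([5.0]))
        assert res["U"] == 0.5
        assert res["p"] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney(np.array([]), np.array([1.0]))


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.cutoff == 3.0
        assert res.direction == ">"

    def test_constant_scores(self):
        res = roc_youden(np.full(10, 2.0), np.array([0, 1] * 5))
        assert res.auc == pytest.approx(0.5)

    def test_null_auc_near_half(self, rng):
        res = roc_youden(rng.random(500), rng.integers(0, 2, 500))
        assert 0.4 <= res.auc <= 0.6

    def test_auc_u_duality_and_trapezoid(self, rng):
        for _ in range(10):
            s = rng.integers(0, 20, 40).astype(float)  # include ties
            y = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            res = roc_youden(s, y)
            want = auc_threshold_oracle(s, y)
            want_dir = max(want, 1 - want)
            assert res.auc == pytest.approx(want_dir, abs=1e-12)

    def test_direction_flips_for_protective_score(self):
        res = roc_youden(np.array([4.0, 3, 2, 1]), np.array([0, 0, 1, 1]))
        assert res.direction == "<"
        assert res.auc == 1.0
        assert res.cutoff == 2.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden(np.array([1.0, 2.0]), np.array([1, 1]))


class TestKmLogrank:
    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        res = km_logrank(t, e, g)
        surv = res.curves["0"].iloc[:, 0]
        for time, val in surv.items():
            assert val == pytest.approx(np.mean(t[g == 0] > time))

    def test_identical_groups_null(self):
        t = np.tile([1.0, 2, 3, 4], 2)
        e = np.ones(8, dtype=int)
        g = np.repeat([0, 1], 4)
        res = km_logrank(t, e, g)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-9)

    def test_chi2_matches_o_minus_e_closed_form(self):
        # small two-group data with censoring, chi2 from the O-E/V form
        t = np.array([6.0, 7, 10, 15, 19, 25, 13, 21, 27, 30, 32, 16])
        e = np.array([1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        res = km_logrank(t, e, g)
        assert res.logrank_chi2 == pytest.approx(logrank_oracle(t, e, g), abs=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(np.array([1.0, 2]), np.array([0, 0]), np.array([0, 1]))


class TestCox:
    def test_tiny_dataset_matches_partial_likelihood_maximum(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0, 1, 0, 1, 0])
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        opt = minimize_scalar(
            lambda b: -cox_loglik_oracle(b, x, t, e), bounds=(-10, 10),
            method="bounded", options={"xatol": 1e-10},
        )
        assert res.summary.loc["x", "coef"] == pytest.approx(opt.x, abs=1e-6)

    def test_enumerated_small_designs_match_oracle(self):
        # every binary covariate pattern on 5 subjects with distinct times
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.ones(5, dtype=int)
        for bits in itertools.product([0.0, 1.0], repeat=5):
            x = np.array(bits)
            if x.min() == x.max():
                continue
            opt = minimize_scalar(
                lambda b: -cox_loglik_oracle(b, x, t, e), bounds=(-15, 15),
                method="bounded", options={"xatol": 1e-10},
            )
            interior = abs(opt.x) < 10  # else the likelihood is monotone
            try:
                res = cox_fit(pd.DataFrame({"x": x}), t, e)
            except RuntimeError:
                assert not interior
                continue
            if interior:
                assert res.summary.loc["x", "coef"] == pytest.approx(opt.x, abs=1e-5)

    def test_global_tests_reported_with_df(self):
        df, _ = gen_cohort(CohortSimParams(n=120, seed=8))
        res = cox_fit(
            df[["skewness_er", "age"]],
            df["followup_time"].to_numpy(),
            df["event"].to_numpy(),
        )
        assert list(res.global_tests.index) == ["likelihood_ratio", "score", "wald"]
        assert (res.global_tests["df"] == 2).all()
        # the three tests agree asymptotically on a clear effect
        chi2 = res.global_tests["chi2"]
        assert chi2.max() / chi2.min() < 1.6
        assert res.summary.loc["skewness_er", "hr"] == pytest.approx(
            np.exp(res.summary.loc["skewness_er", "coef"])
        )

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(
                pd.DataFrame({"x": np.ones(6)}),
                np.arange(1.0, 7.0),
                np.ones(6, dtype=int),
            )

    def test_monotone_likelihood_is_explicit_error(self):
        # perfect separation: all events in one covariate group first
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1, 1, 0, 0, 0])
        with pytest.raises((RuntimeError, ValueError)):
            cox_fit(pd.DataFrame({"x": x}), t, e)


class TestCohortSummary:
    def test_printed_cohort_arithmetic(self):
        table = pd.DataFrame(
            {
                "id": range(38),
                "histology": ["ductal"] * 30 + ["lobular"] * 8,
                "efs8_event": [1] * 11 + [0] * 27,
            }
        )
        s = cohort_summary(table)
        assert s["event_free_pct_crude"] == 71.1
        assert s["categories"]["histology"]["ductal"]["pct"] == 78.9

    def test_zero_events(self):
        table = pd.DataFrame({"id": [1, 2], "efs8_event": [0, 0]})
        assert cohort_summary(table)["event_free_pct_crude"] == 100.0


class TestPipeline:
    def test_planted_cohort_detected_and_deterministic(self):
        df, _ = gen_cohort(CohortSimParams(n=120, seed=21))
        cfg = PipelineConfig(seed=21)
        rep1 = run_paper_pipeline(df, cfg)
        rep2 = run_paper_pipeline(df, cfg)
        assert rep1 == rep2
        mda = rep1["random_forest"]["mean_decrease_accuracy"]
        top3 = sorted(mda, key=mda.get, reverse=True)[:3]
        assert "skewness_er" in top3
        assert "skewness_er" in rep1["km_logrank"]

    def test_report_stages_present(self):
        df, _ = gen_cohort(CohortSimParams(n=80, seed=2))
        rep = run_paper_pipeline(df, PipelineConfig(seed=2))
        for stage in ("spearman", "random_forest", "mann_whitney", "roc",
                      "km_logrank", "cox"):
            assert stage in rep
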