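"""Cohort statistics: fullness, visit averaging, regressions, ROC, PCA, stepwise."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from tmrqc import cohort as ch
from tmrqc.errors import DataIntegrityError, DegenerateInputError, ParameterError


class TestFullness:
    def test_volume_ratio(self):
        assert ch.mw_fullness(10.0, 0.5, 25.0) == pytest.approx(80.0)

    def test_exact_fill(self):
        assert ch.mw_fullness(12.5, 0.5, 25.0) == pytest.approx(100.0)

    def test_overload_accepted(self):
        # overloaded wagons are a real observation, not an error
        assert ch.mw_fullness(13.1, 0.4, 25.0) == pytest.approx(131.0)

    def test_literal_formula_available(self):
        assert ch.mw_fullness(10.0, 0.5, 25.0, literal=True) == pytest.approx(20.0)

    @pytest.mark.parametrize("args", [(0, 0.5, 25), (10, -1, 25), (10, 0.5, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(ParameterError):
            ch.mw_fullness(*args)


class TestVisitAveraging:
    def test_identical_visits_unchanged(self):
        df = pd.DataFrame({"farm": ["a", "a"], "hi": [80.0, 80.0], "mw_type": ["towed"] * 2})
        out = ch.average_repeated_visits(df)
        assert len(out) == 1 and out.loc[0, "hi"] == 80.0 and out.loc[0, "mw_type"] == "towed"

    def test_numeric_fields_averaged(self):
        df = pd.DataFrame({"farm": ["a", "a"], "hi": [70.0, 90.0]})
        assert ch.average_repeated_visits(df).loc[0, "hi"] == 80.0

    def test_57_visits_collapse_to_19_farms(self):
        rng = np.random.default_rng(0)
        farms = np.repeat([f"f{i}" for i in range(19)], 3)[:57]
        df = pd.DataFrame({"farm": farms, "hi": rng.uniform(60, 95, 57)})
        assert len(ch.average_repeated_visits(df)) == 19

    def test_conflicting_categorical_rejected(self):
        df = pd.DataFrame({"farm": ["a", "a"], "hi": [70.0, 90.0],
                           "mw_type": ["towed", "self-propelled"]})
        with pytest.raises(DataIntegrityError):
            ch.average_repeated_visits(df)


class TestNormalityScreen:
    def test_normal_sample_rarely_rejected(self):
        not_rejected = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(100)
            not_rejected += ch.screen_normality(x)["normal"]
        assert not_rejected >= 85  # ~95% expected at alpha = 0.05

    def test_heavy_tails_rejected_with_power(self):
        rejected = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_cauchy(100)
            rejected += not ch.screen_normality(x)["normal"]
        assert rejected > 50

    def test_constant_vector_degenerate(self):
        out = ch.screen_normality(np.full(20, 3.0))
        assert not out["normal"] and "median" in out["summary"]

    def test_summary_form_tracks_decision(self):
        normal = ch.screen_normality(np.random.default_rng(1).standard_normal(200))
        assert set(normal["summary"]) == ({"mean", "sd"} if normal["normal"]
                                          else {"median", "q1", "q3"})


class TestLinearModel:
    def test_noiseless_line_recovered(self):
        x = np.linspace(0, 10, 30)
        rep = ch.linear_model(2.0 * x + 1.0, pd.DataFrame({"x": x}))
        assert rep.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert rep.adj_r2 == pytest.approx(1.0, abs=1e-10)
        assert rep.rse == pytest.approx(0.0, abs=1e-8)

    def test_independent_response_has_no_signal(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        rep = ch.linear_model(y, pd.DataFrame({"x": x}))
        assert abs(rep.params["x"]) < 3.0 * rep.bse["x"] + 0.2
        assert rep.adj_r2 < 0.05

    def test_rank_deficiency_rejected(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(DegenerateInputError):
            ch.linear_model(x, pd.DataFrame({"a": x, "b": 2 * x}))


class TestLogisticModel:
    def test_or_from_2x2_equals_cross_product_ratio(self):
        # 2x2 table: exposed/unexposed vs case/control with counts a,b,c,d
        a, b, c, d = 30, 10, 15, 45
        x = np.array([1] * (a + b) + [0] * (c + d))
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        rep = ch.logistic_model(y, pd.DataFrame({"exposed": x}))
        assert rep.odds_ratios.iloc[0] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_predictor_gives_chance_auc(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        y = rng.integers(0, 2, 200)
        rep = ch.logistic_model(y, pd.DataFrame({"x": x}))
        assert rep.auc == pytest.approx(0.5, abs=0.08)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        rep = ch.logistic_model(y, pd.DataFrame({"x": x}))
        assert rep.separation
        assert np.isnan(rep.odds_ratios.iloc[0])

    def test_auc_equals_mann_whitney_dual(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(300)
        classes = rng.integers(0, 2, 300).astype(bool)
        ours = ch.mann_whitney_auc(scores, classes)
        theirs = roc_auc_score(classes, scores)  # independent trapezoid ROC
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            ch.logistic_model(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestCorrelationScreen:
    def test_self_and_negated_correlations(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"x": x, "x2": x.copy(), "neg": -x})
        out = ch.correlation_screen(df)
        found = {frozenset((r.var_a, r.var_b)): r.r for r in out.itertuples()}
        assert found[frozenset(("x", "x2"))] == pytest.approx(1.0)
        assert found[frozenset(("x", "neg"))] == pytest.approx(-1.0)

    def test_independent_pairs_filtered(self):
        kept = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"a": rng.standard_normal(50), "b": rng.standard_normal(50)})
            kept += len(ch.correlation_screen(df)) > 0
        assert kept <= 1  # |r| >= 0.6 at n=50 under independence is ~never

    def test_spearman_used_for_ordinal(self):
        df = pd.DataFrame({"grade": [1, 1, 2, 2, 3, 3, 4, 4],
                           "score": [1.0, 1.2, 2.1, 2.0, 3.3, 3.1, 4.2, 4.0]})
        out = ch.correlation_screen(df, ordinal=("grade",))
        assert (out["method"] == "spearman").all()

    def test_exceptions_retain_weak_pairs(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a": rng.standard_normal(50), "b": rng.standard_normal(50)})
        out = ch.correlation_screen(df, exceptions=(("a", "b"),))
        assert len(out) == 1


class TestPCA:
    def test_explained_variance_for_known_ratio(self):
        rng = np.random.default_rng(7)
        n = 4000
        a = 3.0 * rng.standard_normal(n)
        b = 1.0 * rng.standard_normal(n)
        # rotate so neither axis is trivially a variable, variance ratio 9:1
        df = pd.DataFrame({"x": (a + b) / np.sqrt(2), "y": (a - b) / np.sqrt(2)})
        out = ch.pca_summary(df, n_components=2)
        ev = out["explained_variance_pct"].to_numpy()
        assert ev[0] == pytest.approx(90.0, abs=2.0)
        assert ev[1] == pytest.approx(10.0, abs=2.0)

    def test_variances_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((60, 6)), columns=list("abcdef"))
        ev = ch.pca_summary(df)["explained_variance_pct"].to_numpy()
        assert np.all(np.diff(ev) <= 1e-9)
        assert ev.sum() <= 100.0 + 1e-6

    def test_duplicated_column_dominates_first_component(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(80)
        df = pd.DataFrame({"x": x, "x2": x.copy(), "noise": rng.standard_normal(80)})
        out = ch.pca_summary(df)
        loadings = out["loadings"]["PC1"].abs()
        assert loadings["x"] > loadings["noise"]
        assert loadings["x2"] > loadings["noise"]

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x": rng.standard_normal(30), "flat": np.ones(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = ch.pca_summary(df)
        assert out["dropped"] == ["flat"]


class TestStepwiseAIC:
    def test_exact_duplicate_pruned_by_vif(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"x": x, "dup": x.copy(), "z": rng.standard_normal(100)})
        rep = ch.stepwise_aic(x + 0.1 * rng.standard_normal(100), X)
        assert rep.vif is None or (rep.vif < 10).all()
        assert not ({"x", "dup"} <= set(rep.selected))

    def test_true_predictors_recovered(self):
        # AIC admits a spurious null predictor with ~16% probability each, so
        # the check is superset recovery plus a bound on false inclusions
        contains_truth, spurious = 0, []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((200, 6)), columns=list("abcdef"))
            y = 2.0 * X["b"] - 1.5 * X["e"] + 0.1 * rng.standard_normal(200)
            rep = ch.stepwise_aic(y, X)
            contains_truth += {"b", "e"} <= set(rep.selected)
            spurious.append(len(set(rep.selected) - {"b", "e"}))
        assert contains_truth >= 49
        assert np.mean(spurious) < 1.5  # ~4 * 0.157 expected

    def test_null_response_keeps_model_small(self):
        # intercept-only is the modal outcome; AIC keeps ~0.6 spurious terms
        empties, sizes = 0, []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
            rep = ch.stepwise_aic(rng.standard_normal(100), X)
            empties += len(rep.selected) == 0
            sizes.append(len(rep.selected))
        assert empties >= 14  # P(empty) = (1 - 0.157)^4 ~ 0.50
        assert np.mean(sizes) <= 1.2

    def test_median_yield_split(self):
        df = pd.DataFrame({"milk_yield": [30.0, 32.0, 34.0, 36.0]})
        labels = ch.split_by_median_yield(df)
        assert list(labels) == ["FMY-low", "FMY-low", "FMY-high", "FMY-high"]
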