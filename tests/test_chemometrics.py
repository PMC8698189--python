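"""Pretreatments, splitting, outlier diagnostics, PLS fitting and metrics."""

import numpy as np
import pytest

from tmrqc import chemometrics as cm
from tmrqc.errors import DegenerateInputError, ParameterError

WL = np.arange(902.0, 1660.0 + 1e-9, 2.0)


def spec(absorbance, wl=WL):
    return cm.Spectrum(wl, np.asarray(absorbance, dtype=float))


class TestSNV:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = cm.snv(spec(rng.standard_normal(len(WL)) * 3 + 5))
        assert out.absorbance.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.absorbance.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(len(WL))
        a = cm.snv(spec(x)).absorbance
        b = cm.snv(spec(2.5 * x + 7.0)).absorbance
        assert np.allclose(a, b, atol=1e-10)

    def test_two_point_closed_form(self):
        wl2 = np.array([1000.0, 1002.0])
        out = cm.snv(cm.Spectrum(wl2, np.array([0.0, 2.0])))
        assert np.allclose(out.absorbance, [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            cm.snv(spec(np.full(len(WL), 3.0)))


class TestDetrend:
    def test_annihilates_quadratic(self):
        u = (WL - WL.mean()) / 100.0
        out = cm.detrend(spec(1.0 + 0.5 * u - 0.2 * u**2), degree=2)
        assert np.max(np.abs(out.absorbance)) < 1e-9

    def test_degree_zero_is_mean_centering(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(len(WL))
        out = cm.detrend(spec(x), degree=0)
        assert np.allclose(out.absorbance, x - x.mean(), atol=1e-10)

    def test_planted_band_recovered_from_quadratic_baseline(self):
        u = (WL - WL.mean()) / (np.ptp(WL) / 2.0)
        baseline = 2.0 + 1.0 * u + 0.5 * u**2
        band = 0.3 * np.exp(-0.5 * ((WL - 1450.0) / 30.0) ** 2)
        out = cm.detrend(spec(baseline + band), degree=2).absorbance
        # independent oracle: band minus its own quadratic projection (polyfit)
        proj = np.polyval(np.polyfit(u, band, 2), u)
        assert np.allclose(out, band - proj, atol=1e-8)
        # baseline itself is annihilated to < 1e-6 of its magnitude
        resid = cm.detrend(spec(baseline), degree=2).absorbance
        assert np.max(np.abs(resid)) < 1e-6 * np.max(np.abs(baseline))


class TestSavitzkyGolay:
    def test_derivative_of_linear_ramp_is_slope(self):
        m = 0.003  # absorbance per nm
        out = cm.smooth_and_derivative(spec(m * (WL - 902.0)), window=7, poly=2, deriv_order=1)
        assert np.allclose(out.absorbance, m, atol=1e-9)

    def test_derivative_of_constant_is_zero(self):
        out = cm.smooth_and_derivative(spec(np.full(len(WL), 1.3)), deriv_order=1)
        assert np.allclose(out.absorbance, 0.0, atol=1e-12)

    def test_smoothing_reduces_white_noise_variance(self):
        rng = np.random.default_rng(3)
        reduced = 0
        for _ in range(100):
            x = rng.standard_normal(len(WL))
            sm = cm.smooth_and_derivative(spec(x), window=11, poly=2, deriv_order=0)
            reduced += sm.absorbance.var() < x.var()
        assert reduced == 100

    def test_length_preserved(self):
        out = cm.smooth_and_derivative(spec(np.sin(WL / 50.0)), window=9, poly=3)
        assert len(out.absorbance) == len(WL)

    @pytest.mark.parametrize("window, poly, order", [(6, 2, 0), (7, 7, 0), (7, 2, 2), (5, 1, 1)])
    def test_invalid_parameters(self, window, poly, order):
        x = spec(np.sin(WL / 50.0))
        if (window, poly, order) == (5, 1, 1):  # valid combination, sanity anchor
            cm.smooth_and_derivative(x, window=window, poly=poly, deriv_order=order)
        else:
            with pytest.raises(ParameterError):
                cm.smooth_and_derivative(x, window=window, poly=poly, deriv_order=order)


class TestSplit:
    def test_55_45_split(self):
        c, v = cm.split_calibration_validation(100, seed=0)
        assert len(c) == 55 and len(v) == 45

    def test_round_half_up_small_n(self):
        c, v = cm.split_calibration_validation(10, seed=0)
        assert len(c) == 6 and len(v) == 4

    def test_deterministic_disjoint_exhaustive(self):
        c1, v1 = cm.split_calibration_validation(73, seed=11)
        c2, v2 = cm.split_calibration_validation(73, seed=11)
        assert np.array_equal(c1, c2) and np.array_equal(v1, v2)
        assert len(np.intersect1d(c1, v1)) == 0
        assert len(np.union1d(c1, v1)) == 73

    def test_different_seeds_differ(self):
        c1, _ = cm.split_calibration_validation(100, seed=1)
        c2, _ = cm.split_calibration_validation(100, seed=2)
        assert not np.array_equal(c1, c2)


class TestCooksD:
    @pytest.mark.parametrize(
        "t, h, k, expected",
        [(0.0, 0.3, 2, 0.0), (1.0, 0.5, 1, 0.5), (2.0, 0.2, 4, 0.2)],
    )
    def test_closed_form(self, t, h, k, expected):
        assert cm.cooks_d(t, h, k) == pytest.approx(expected, abs=1e-12)

    def test_leverage_bounds(self):
        with pytest.raises(ParameterError):
            cm.cooks_d(1.0, 1.0, 2)
        with pytest.raises(ParameterError):
            cm.cooks_d(1.0, -0.1, 2)


class TestOutlierDetection:
    def test_clean_null_rarely_flags(self):
        flag_free = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = rng.standard_normal((100, 3))
            resid = rng.standard_normal(100)
            flagged, _ = cm.detect_outliers(scores, resid, n_factors=3)
            flag_free += len(flagged) == 0
            assert len(flagged) <= 20  # never removes >20% of a clean set
        assert flag_free >= 95

    def test_planted_score_outlier_flagged(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal((80, 3))
        scores[17] += 10.0  # 10 pooled-SD shift in score space
        flagged, diag = cm.detect_outliers(scores, rng.standard_normal(80), n_factors=3)
        assert 17 in flagged
        assert diag["mahalanobis"][17] > 3.0

    def test_infinite_thresholds_flag_nothing(self):
        rng = np.random.default_rng(5)
        flagged, _ = cm.detect_outliers(
            rng.standard_normal((50, 2)), rng.standard_normal(50), 2,
            mahalanobis_threshold=np.inf, cooks_threshold=np.inf,
        )
        assert len(flagged) == 0


class TestFitPLS:
    def test_noiseless_single_latent_selects_one_factor(self):
        rng = np.random.default_rng(6)
        t = rng.standard_normal(60)
        direction = rng.standard_normal(40)
        X = np.outer(t, direction)
        model = cm.fit_pls(X, 2.0 * t + 1.0, trait="latent", seed=0)
        assert model.n_factors == 1
        assert model.rmse_cv < 1e-8
        assert model.r2_cv > 0.999

    def test_univariate_pls_equals_ols(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        y = 3.0 * x + 0.5 + 0.2 * rng.standard_normal(40)
        model = cm.fit_pls(
            x[:, None], y, max_factors=1, seed=0,
            mahalanobis_threshold=np.inf, cooks_threshold=np.inf,
        )
        slope, intercept = np.polyfit(x, y, 1)  # independent OLS oracle
        assert np.allclose(model.predict(x[:, None]), slope * x + intercept, atol=1e-9)

    def test_max_factors_honoured(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((80, 60))
        y = X @ rng.standard_normal(60) + 0.01 * rng.standard_normal(80)
        model = cm.fit_pls(X, y, max_factors=10, seed=0)
        assert 1 <= model.n_factors <= 10

    def test_records_outlier_bookkeeping(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 20))
        y = X[:, 0] + 0.1 * rng.standard_normal(60)
        X[3] += 12.0  # gross spectral outlier
        model = cm.fit_pls(X, y, seed=0, sample_ids=[f"s{i}" for i in range(60)])
        assert model.ncal == 60 - model.n_outliers_removed
        assert "s3" in model.removed_outliers

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            cm.fit_pls(np.zeros((5, 3)), np.zeros(5))


class TestEvaluate:
    @staticmethod
    def _model_and_data(seed=10, n=120):
        rng = np.random.default_rng(seed)
        t = rng.standard_normal(n)
        X = np.outer(t, rng.standard_normal(30)) + 0.01 * rng.standard_normal((n, 30))
        y = 2.0 * t + 5.0 + 0.05 * rng.standard_normal(n)
        model = cm.fit_pls(X[:70], y[:70], seed=0)
        return model, X[70:], y[70:]

    def test_perfect_predictions(self):
        model, Xv, _ = self._model_and_data()
        yv = model.predict(Xv)  # make actuals equal the predictions
        report = cm.evaluate(model, Xv, yv)
        assert report.rmse_v == pytest.approx(0.0, abs=1e-10)
        assert report.r2_v == pytest.approx(1.0, abs=1e-10)
        assert report.skew == pytest.approx(1.0, abs=1e-10)

    def test_rmse_matches_independent_computation(self):
        model, Xv, yv = self._model_and_data(seed=11, n=50 + 70)
        report = cm.evaluate(model, Xv, yv)
        resid = yv - model.predict(Xv)
        hand = float(np.sqrt(sum(r * r for r in resid) / len(resid)))
        assert report.rmse_v == pytest.approx(hand, abs=1e-12)

    def test_constant_predictions_have_undefined_skew(self):
        model, Xv, yv = self._model_and_data(seed=12)
        model.coef = np.zeros_like(model.coef)  # force mean-only predictions
        report = cm.evaluate(model, Xv, yv)
        assert np.isnan(report.skew)
        assert report.r2_v <= 0.0

    def test_gh_near_one_for_in_population_validation(self):
        model, Xv, yv = self._model_and_data(seed=13)
        report = cm.evaluate(model, Xv, yv)
        assert 0.2 < report.gh < 5.0

    def test_empty_validation_rejected(self):
        model, Xv, yv = self._model_and_data(seed=14)
        with pytest.raises(cm.InputValidationError):
            cm.evaluate(model, Xv[:0], yv[:0])


class TestModelArchive:
    def test_json_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((40, 15))
        y = X[:, 0] - X[:, 3] + 0.1 * rng.standard_normal(40)
        model = cm.fit_pls(X, y, trait="demo", seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = cm.CalibrationModel.load(path)
        assert loaded.trait == "demo"
        assert np.allclose(loaded.predict(X), model.predict(X), atol=1e-12)


class TestChainPurity:
    def test_chain_is_pure_and_order_sensitive(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((5, len(WL))) + 3.0
        X_copy = X.copy()
        a = cm.PretreatmentChain([("snv", {}), ("detrend", {"degree": 1})])
        b = cm.PretreatmentChain([("detrend", {"degree": 1}), ("snv", {})])
        out_a, out_b = a.apply_matrix(X, WL), b.apply_matrix(X, WL)
        assert np.array_equal(X, X_copy)  # inputs never mutated
        assert not np.allclose(out_a, out_b)
        assert np.allclose(a.apply_matrix(X, WL), out_a)  # deterministic
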