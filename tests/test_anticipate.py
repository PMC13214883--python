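import numpy as np
import pytest

import ramancast as rc
from ramancast.anticipate import (
    AnticipationConfig,
    PcaModel,
    SpectrumForecast,
    SpectrumForecaster,
    WindowScores,
    accumulate_window,
    anticipate,
    baseline_anticipate,
    fit_trend,
    fit_window_pca,
)
from ramancast.errors import (
    ConfigError,
    DegeneratePredictorError,
    DegenerateWindowError,
    InsufficientDataError,
)

from conftest import make_series


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(window_h=0.0), dict(n_components=4), dict(pc1_fit="spline"),
         dict(ridge_lambda=-1.0), dict(min_window_spectra=2)],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            AnticipationConfig(**kwargs)


class TestAccumulateWindow:
    def test_hourly_window_holds_five_spectra(self):
        s = make_series(np.arange(0.0, 31.0), lambda t, ax: np.sin(ax + t))
        w = accumulate_window(s, 20.0, 5.0)
        assert [x.time_h for x in w] == [16.0, 17.0, 18.0, 19.0, 20.0]

    def test_half_hourly_window_holds_ten_spectra(self):
        s = make_series(np.arange(0.0, 30.5, 0.5), lambda t, ax: np.sin(ax + t))
        w = accumulate_window(s, 20.0, 5.0)
        assert [x.time_h for x in w] == [15.5 + 0.5 * k for k in range(10)]

    def test_minimum_count_boundary(self):
        s = make_series(np.arange(0.0, 11.0), lambda t, ax: np.sin(ax + t))
        w = accumulate_window(s, 2.0, 5.0, min_window_spectra=3)
        assert [x.time_h for x in w] == [0.0, 1.0, 2.0]
        with pytest.raises(InsufficientDataError):
            accumulate_window(s, 1.0, 5.0, min_window_spectra=3)

    def test_anchor_before_series_rejected(self):
        s = make_series([5.0, 6.0, 7.0], lambda t, ax: np.sin(ax + t))
        with pytest.raises(InsufficientDataError):
            accumulate_window(s, 2.0, 5.0)


def rank2_window(n=5, seed=0):
    """Spectra lying exactly in a 2-D affine subspace of spectrum space."""
    rng = np.random.default_rng(seed)
    axis = np.arange(100.0, 160.0)
    m = rng.standard_normal(axis.size)
    v1 = rng.standard_normal(axis.size)
    v2 = rng.standard_normal(axis.size)
    times = np.arange(float(n))
    rows = [m + t * v1 + (2 + 3 * t + 0.5 * t**2) * v2 for t in times]
    return [rc.Spectrum(axis, r, t) for r, t in zip(rows, times)]


class TestWindowPca:
    def test_rank2_data_fully_explained_by_two_components(self):
        model, scores = fit_window_pca(rank2_window(), 2)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_dominant_direction_exceeds_80_percent(self, yeast_series):
        series, _ = yeast_series
        w = accumulate_window(series, 30.0, 5.0)
        model, _ = fit_window_pca(w, 2)
        assert model.explained_variance_ratio[0] > 0.80

    def test_eckart_young_residual_identity(self, yeast_series):
        # residual^2 / centred-norm^2 == 1 - sum(evr); oracle = raw SVD
        series, _ = yeast_series
        w = accumulate_window(series, 40.0, 5.0)
        model, scores = fit_window_pca(w, 2)
        X = np.vstack([s.intensities for s in w])
        Xc = X - X.mean(axis=0)
        recon = scores.scores @ model.loadings
        ratio = np.sum((Xc - recon) ** 2) / np.sum(Xc**2)
        assert ratio == pytest.approx(
            1.0 - model.explained_variance_ratio.sum(), abs=1e-8
        )
        # independent oracle: singular values of the centred matrix
        sv = np.linalg.svd(Xc, compute_uv=False)
        np.testing.assert_allclose(
            model.explained_variance_ratio,
            sv[:2] ** 2 / np.sum(sv**2),
            atol=1e-10,
        )

    def test_scores_are_projections_onto_loadings(self):
        w = rank2_window()
        model, scores = fit_window_pca(w, 2)
        X = np.vstack([s.intensities for s in w])
        expected = (X - model.mean_spectrum) @ model.loadings.T
        np.testing.assert_allclose(scores.scores, expected, atol=1e-9)

    def test_window_too_small_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_window_pca(rank2_window(n=2), 2)

    def test_constant_window_rejected(self):
        axis = np.arange(100.0, 150.0)
        w = [rc.Spectrum(axis, np.ones(axis.size), t) for t in range(5)]
        with pytest.raises(DegenerateWindowError):
            fit_window_pca(w, 2)


class TestFitTrend:
    def test_exact_line(self):
        fit = fit_trend([0.0, 1.0, 2.0], [1.0, 3.0, 5.0], "linear")
        np.testing.assert_allclose(fit.coefficients, (1.0, 2.0), atol=1e-12)

    def test_exact_parabola(self):
        fit = fit_trend([0.0, 1.0, 2.0], [0.0, 1.0, 4.0], "quadratic")
        np.testing.assert_allclose(fit.coefficients, (0.0, 0.0, 1.0), atol=1e-12)

    def test_exact_cubic(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_trend(x, 2 - x + 0.5 * x**3, "cubic")
        np.testing.assert_allclose(fit.coefficients, (2.0, -1.0, 0.0, 0.5), atol=1e-10)

    def test_ridge_at_zero_penalty_equals_ols(self):
        # oracle: closed-form normal equations for the straight line
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([0.2, 0.9, 2.1, 4.3])
        fit = fit_trend(x, y, "ridge", ridge_lambda=0.0)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)

    def test_ridge_shrinks_slope_towards_zero(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.0 * x
        slopes = [
            fit_trend(x, y, "ridge", ridge_lambda=lam).coefficients[1]
            for lam in (0.0, 1.0, 10.0)
        ]
        assert slopes[0] == pytest.approx(2.0, abs=1e-10)
        assert slopes[0] > slopes[1] > slopes[2] > 0

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fit_trend([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], "linear")


class TestAnticipate:
    def test_exact_on_linear_latent_dynamics(self):
        # s(t) = m + t v1 + (2 + 3t) v2: the model class contains the truth,
        # so anticipation reproduces the future spectrum exactly at any
        # horizon. Oracle: direct evaluation of s(t + h).
        rng = np.random.default_rng(7)
        axis = np.arange(100.0, 180.0)
        m = rng.standard_normal(axis.size) * 5
        v1, v2 = rng.standard_normal(axis.size), rng.standard_normal(axis.size)
        s = lambda t: m + t * v1 + (2 + 3 * t) * v2
        series = make_series(np.arange(0.0, 61.0), lambda t, ax: s(t), axis=axis)
        for anchor, horizon in [(20.0, 1.0), (25.0, 10.0), (30.0, 30.0)]:
            result = anticipate(series, anchor, horizon)
            truth = s(anchor + horizon)
            err = np.linalg.norm(result.predicted.intensities - truth)
            assert err < 1e-6 * np.linalg.norm(truth)

    def test_exact_on_linear_exact_preset(self, linear_exact_series):
        series, _ = linear_exact_series
        result = anticipate(series, 30.0, 20.0)
        actual = series.at(50.0)
        err = np.linalg.norm(result.predicted.intensities - actual.intensities)
        assert err < 1e-6 * np.linalg.norm(actual.intensities)

    def test_small_horizon_matches_trend_value_at_anchor(self, yeast_series):
        # continuity: as h -> 0+ the prediction tends to the rank-2 trend
        # reconstruction at the anchor (a regression value, not the raw
        # last spectrum)
        series, _ = yeast_series
        fc = SpectrumForecaster(series).fit(40.0)
        tiny = fc.predict(1e-9).predicted.intensities
        pc1 = fc.fits[0].predict(40.0)
        expected = fc.pca.inverse_transform(
            np.array([pc1, fc.fits[1].predict(pc1)])
        )
        np.testing.assert_allclose(tiny, expected, atol=1e-6)

    def test_anchor_before_start_rejected(self, yeast_series):
        series, _ = yeast_series
        with pytest.raises(ConfigError):
            anticipate(series, 10.0, 5.0, AnticipationConfig(start_h=20.0))

    def test_constant_series_degenerate(self):
        s = make_series(np.arange(0.0, 30.0), lambda t, ax: np.ones(ax.size))
        with pytest.raises(DegenerateWindowError):
            anticipate(s, 20.0, 5.0, AnticipationConfig(start_h=0.0))

    def test_three_component_variant_runs(self, yeast_series):
        series, _ = yeast_series
        cfg = AnticipationConfig(n_components=3)
        result = anticipate(series, 40.0, 5.0, cfg)
        assert len(result.predicted_scores) == 3
        assert result.pca.loadings.shape[0] == 3

    def test_sign_flip_invariance_of_pipeline(self, yeast_series):
        # negating any loading together with its scores must leave the
        # anticipated spectrum unchanged
        series, _ = yeast_series
        cfg = AnticipationConfig()
        fc = SpectrumForecaster(series, cfg).fit(35.0)
        reference = fc.predict(8.0).predicted.intensities
        for k in (0, 1):
            loadings = fc.pca.loadings.copy()
            scores = fc.scores.scores.copy()
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
            pca = PcaModel(
                fc.pca.mean_spectrum, loadings, fc.pca.explained_variance_ratio
            )
            ws = WindowScores(fc.scores.times, scores)
            fits = (
                fit_trend(ws.times, ws.pc1, cfg.pc1_fit, cfg.ridge_lambda, "time"),
                fit_trend(ws.pc1, ws.pc2, cfg.pc2_fit, cfg.ridge_lambda, "pc1"),
            )
            flipped = SpectrumForecast(
                model=fc.model, anchor_h=fc.anchor_h, pca=pca, scores=ws, fits=fits
            )
            np.testing.assert_allclose(
                flipped.predict(8.0).predicted.intensities, reference, atol=1e-8
            )

    def test_rank2_window_reconstruction_exact(self):
        w = rank2_window()
        model, scores = fit_window_pca(w, 2)
        X = np.vstack([s.intensities for s in w])
        recon = model.inverse_transform(scores.scores)
        err = np.linalg.norm(recon - X) / np.linalg.norm(X - X.mean(axis=0))
        assert err < 1e-8

    def test_summary_reports_fit(self, yeast_series):
        series, _ = yeast_series
        text = SpectrumForecaster(series).fit(30.0).summary()
        assert "PC1 ~ time" in text and "explained variance" in text


class TestBaseline:
    def test_copies_anchor_spectrum(self, yeast_series):
        series, _ = yeast_series
        result = baseline_anticipate(series, 20.0, 10.0)
        np.testing.assert_array_equal(
            result.predicted.intensities, series.at(20.0).intensities
        )
        assert result.predicted.time_h == 30.0

    def test_horizon_independence(self, yeast_series):
        series, _ = yeast_series
        a = baseline_anticipate(series, 20.0, 1.0)
        b = baseline_anticipate(series, 20.0, 30.0)
        np.testing.assert_array_equal(
            a.predicted.intensities, b.predicted.intensities
        )

    def test_off_grid_anchor_floors(self, yeast_series):
        series, _ = yeast_series
        result = baseline_anticipate(series, 19.5, 2.0)
        np.testing.assert_array_equal(
            result.predicted.intensities, series.at(19.0).intensities
        )

    def test_no_spectrum_before_anchor_rejected(self):
        s = make_series([10.0, 11.0, 12.0], lambda t, ax: np.sin(ax + t))
        with pytest.raises(InsufficientDataError):
            baseline_anticipate(s, 5.0, 1.0)
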