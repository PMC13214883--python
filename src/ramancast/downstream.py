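"""Plug-and-play demo: anticipated spectra fed to a spectral OD model.

Spectra anticipation is model-agnostic: any chemometrics model that maps a
spectrum to a process quantity can consume anticipated spectra unchanged.
This module demonstrates the plumbing with a deliberately simple, fully
transparent stand-in — a ridge-regularised linear map from the (optionally
d2-detrended) spectrum to OD650, with the penalty chosen by
leave-one-batch-out cross-validation over a small fixed grid. It is a
stand-in chemometrics model for demonstration, not a production biomass
model.

Per-horizon RMSE of anticipated-spectrum OD is reported relative to the OD
the same model produces from the *actual* spectrum (so the comparison
isolates the anticipation error from the chemometrics error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .anticipate import AnticipationConfig, SpectrumForecaster, baseline_anticipate
from .errors import RamancastError, ValidationError
from .io import SpectraSeries, Spectrum
from .preprocess import DetrendConfig, d2_detrend
from .synthetic import GroundTruth

__all__ = ["OdModel", "OdComparison", "fit_od_model", "od_trajectory_comparison"]

logger = logging.getLogger(__name__)

_ALPHA_GRID = (1e-10, 1e-6, 1e-2, 1.0, 100.0)


@dataclass
class OdModel:
    """Ridge-linear spectrum -> OD map (the stand-in chemometrics model)."""

    coefficients: np.ndarray
    intercept: float
    alpha: float
    preprocess: DetrendConfig | None
    training_batches: tuple

    def predict_spectrum(self, spectrum: Spectrum) -> float:
        if spectrum.n_channels != self.coefficients.size:
            raise ValidationError("spectrum axis does not match the OD model")
        if self.preprocess is not None:
            spectrum = d2_detrend(spectrum, self.preprocess)
        return float(spectrum.intensities @ self.coefficients + self.intercept)

    def predict(self, series: SpectraSeries) -> np.ndarray:
        return np.array([self.predict_spectrum(s) for s in series])


def _design(series: SpectraSeries, preprocess: DetrendConfig | None) -> np.ndarray:
    if preprocess is None:
        return series.intensity_matrix()
    return np.vstack([d2_detrend(s, preprocess).intensities for s in series])


def _aligned_od(series: SpectraSeries, truth: GroundTruth) -> np.ndarray:
    return np.interp(series.times, truth.times, truth.od)


def fit_od_model(
    training,
    preprocess: DetrendConfig | None = None,
    alphas=_ALPHA_GRID,
) -> OdModel:
    """Fit the stand-in OD model on >= 2 (SpectraSeries, GroundTruth) pairs.

    The ridge penalty is selected by leave-one-batch-out validation RMSE
    over ``alphas``, then the model is refit on all batches. Deterministic
    for a given training set and configuration.
    """
    training = list(training)
    if len(training) < 2:
        raise ValidationError("need >= 2 training batches for the OD model")
    Xs = [_design(series, preprocess) for series, _ in training]
    ys = [_aligned_od(series, truth) for series, truth in training]

    best_alpha, best_err = None, np.inf
    for alpha in alphas:
        errs = []
        for held in range(len(training)):
            Xtr = np.vstack([X for i, X in enumerate(Xs) if i != held])
            ytr = np.concatenate([y for i, y in enumerate(ys) if i != held])
            model = Ridge(alpha=alpha, solver="svd").fit(Xtr, ytr)
            pred = model.predict(Xs[held])
            errs.append(np.mean((pred - ys[held]) ** 2))
        err = float(np.sqrt(np.mean(errs)))
        if err < best_err:
            best_alpha, best_err = alpha, err

    final = Ridge(alpha=best_alpha, solver="svd").fit(np.vstack(Xs), np.concatenate(ys))
    return OdModel(
        coefficients=np.asarray(final.coef_, dtype=float),
        intercept=float(final.intercept_),
        alpha=float(best_alpha),
        preprocess=preprocess,
        training_batches=tuple(series.batch_id for series, _ in training),
    )


@dataclass
class OdComparison:
    """Actual vs spectrum-predicted vs anticipated-spectrum-predicted OD."""

    table: pd.DataFrame
    rmse_by_horizon: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def od_trajectory_comparison(
    model: OdModel,
    series: SpectraSeries,
    truth: GroundTruth,
    horizons,
    cfg: AnticipationConfig | None = None,
    method: str = "anticipation",
) -> OdComparison:
    """OD trajectories of one batch: measured, from the actual spectrum, and
    from the spectrum anticipated ``h`` hours earlier, for each horizon.

    Time points whose anchor (``t - h``) falls before ``cfg.start_h`` or off
    the acquisition grid are left blank; per-horizon RMSE is computed for
    the remaining rows, relative to the chemometrics (actual-spectrum) OD.
    """
    cfg = cfg or AnticipationConfig()
    if model.coefficients.size != series.axis.size:
        raise ValidationError("OD model axis does not match the series")
    times = series.times
    table = pd.DataFrame(
        {
            "time_h": times,
            "od_actual": _aligned_od(series, truth),
            "od_from_actual_spectrum": model.predict(series),
        }
    )
    rmse_by_horizon: dict = {}
    forecaster = SpectrumForecaster(series, cfg)
    for h in horizons:
        col = np.full(times.size, np.nan)
        for k, t in enumerate(times):
            anchor = t - h
            if anchor < cfg.start_h - 1e-9 or series.at(anchor) is None:
                continue
            try:
                if method == "anticipation":
                    result = forecaster.fit(float(anchor)).predict(float(h))
                else:
                    result = baseline_anticipate(series, float(anchor), float(h))
            except RamancastError as exc:
                logger.warning("anchor %g h horizon %g h skipped: %s", anchor, h, exc)
                continue
            col[k] = model.predict_spectrum(result.predicted)
        name = f"od_from_anticipated_{h:g}h"
        table[name] = col
        ok = ~np.isnan(col)
        if ok.any():
            diff = col[ok] - table["od_from_actual_spectrum"].to_numpy()[ok]
            rmse_by_horizon[float(h)] = float(np.sqrt(np.mean(diff**2)))
        else:
            logger.warning("horizon %g h: no valid anchors, rows omitted", h)
    return OdComparison(table=table, rmse_by_horizon=rmse_by_horizon)
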