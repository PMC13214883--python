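"""Evaluation of anticipated spectra: cosine similarity, delta-tmin, tables.

An anticipated spectrum targeting time ``j`` is compared (cosine similarity)
against *every* actual spectrum of the same batch, past and future, window
included. ``tmin`` is the time of the most similar actual spectrum and
``delta_tmin = tmin - j``; an ideal method yields 0 at every horizon, while
the naive last-spectrum baseline yields exactly ``-horizon`` on a regular
grid of pairwise-distinct spectra (its copy of the anchor spectrum matches
itself with similarity 1). Per-horizon means and standard deviations of
delta_tmin, pooled over anchors and batches, form the summary tables; RMSE
and Pearson correlation are the conventional per-spectrum comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anticipate import (
    AnticipationConfig,
    AnticipationResult,
    SpectrumForecaster,
    baseline_anticipate,
)
from .errors import UndefinedSimilarityError, ValidationError
from .io import SpectraSeries
from .preprocess import DetrendConfig, d2_detrend

__all__ = [
    "SimilarityProfile",
    "HorizonSummary",
    "cosine_similarity",
    "similarity_profile",
    "evaluate_series",
    "aggregate_horizons",
    "summaries_to_frame",
    "rmse",
    "pearson",
]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityProfile:
    """Similarities of one anticipated spectrum against a whole batch."""

    target_time_j: float
    horizon_i: float
    times: np.ndarray
    similarities: np.ndarray
    tmin: float
    delta_tmin: float

    def plot(self, ax=None):
        """Similarity against batch time, with tmin and the target marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.times, self.similarities, ".-")
        ax.axvline(self.target_time_j, ls="--", color="k", label="target j")
        ax.axvline(self.tmin, ls=":", color="r", label="tmin")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cosine similarity")
        ax.legend()
        return ax


@dataclass
class HorizonSummary:
    """Pooled delta_tmin statistics at one anticipation horizon."""

    horizon_i: float
    mean_delta: float
    sd_delta: float
    n: int


def cosine_similarity(A, B) -> float:
    """Cosine of the angle between two intensity vectors,
    ``A.B / (||A|| ||B||)``; scale-invariant, in [-1, 1]."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 1:
        raise ValidationError("cosine similarity needs equal-length vectors")
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("zero-norm vector has no direction")
    return float(np.clip(A @ B / (na * nb), -1.0, 1.0))


def similarity_profile(
    predicted: AnticipationResult,
    series: SpectraSeries,
    preprocess: DetrendConfig | None = None,
) -> SimilarityProfile:
    """Compare a prediction against every actual spectrum of its batch.

    The optional d2 detrending is applied identically to both sides before
    comparison. Ties in similarity resolve to the candidate closest in time
    to the target, then to the earlier time.
    """
    if predicted.predicted.wavenumbers.size != series.axis.size or not np.array_equal(
        predicted.predicted.wavenumbers, series.axis
    ):
        raise ValidationError("prediction and series are on different axes")

    pred_spec = predicted.predicted
    actuals = list(series)
    if preprocess is not None:
        pred_spec = d2_detrend(pred_spec, preprocess)
        actuals = [d2_detrend(s, preprocess) for s in actuals]

    times = np.array([s.time_h for s in actuals])
    sims = np.array(
        [cosine_similarity(pred_spec.intensities, s.intensities) for s in actuals]
    )
    j = predicted.target_time_h
    # argmax similarity; break ties by |t - j| then by earlier time
    order = np.lexsort((times, np.abs(times - j), -sims))
    tmin = float(times[order[0]])
    return SimilarityProfile(
        target_time_j=float(j),
        horizon_i=float(predicted.horizon_h),
        times=times,
        similarities=sims,
        tmin=tmin,
        delta_tmin=tmin - float(j),
    )


def evaluate_series(
    series: SpectraSeries,
    horizons,
    method: str = "anticipation",
    cfg: AnticipationConfig | None = None,
    preprocess: DetrendConfig | None = None,
) -> list[SimilarityProfile]:
    """One similarity profile per (anchor, horizon) over a whole batch.

    Anchors are every acquisition time from ``cfg.start_h`` onward whose
    target ``anchor + horizon`` still lies within the batch. An empty
    result (no valid anchors) is returned with a warning, not an error.
    """
    cfg = cfg or AnticipationConfig()
    if method not in ("anticipation", "baseline"):
        raise ValidationError(f"unknown method {method!r}")
    profiles: list[SimilarityProfile] = []
    times = series.times
    last = times[-1] if len(series) else -np.inf
    for horizon in horizons:
        anchors = times[
            (times >= cfg.start_h - 1e-9) & (times + horizon <= last + 1e-9)
        ]
        if anchors.size == 0:
            logger.warning(
                "batch %s: no valid anchors for horizon %g h", series.batch_id, horizon
            )
            continue
        if method == "anticipation":
            forecaster = SpectrumForecaster(series, cfg)
            for a in anchors:
                result = forecaster.fit(float(a)).predict(float(horizon))
                profiles.append(similarity_profile(result, series, preprocess))
        else:
            for a in anchors:
                result = baseline_anticipate(series, float(a), float(horizon))
                profiles.append(similarity_profile(result, series, preprocess))
    if not profiles:
        logger.warning("batch %s: no profiles produced", series.batch_id)
    return profiles


def aggregate_horizons(profiles) -> list[HorizonSummary]:
    """Pool delta_tmin per horizon across anchors and batches.

    Mean and sample (n-1) standard deviation; groups of one report sd 0.
    """
    df = pd.DataFrame(
        {
            "horizon_i": [p.horizon_i for p in profiles],
            "delta_tmin": [p.delta_tmin for p in profiles],
        }
    )
    out: list[HorizonSummary] = []
    for horizon, grp in df.groupby("horizon_i", sort=True):
        vals = grp["delta_tmin"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(
            HorizonSummary(
                horizon_i=float(horizon),
                mean_delta=float(vals.mean()),
                sd_delta=sd,
                n=int(vals.size),
            )
        )
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tabular form of horizon summaries (the machine twin of the
    mean ± sd delta_tmin tables)."""
    return pd.DataFrame(
        {
            "horizon_h": [s.horizon_i for s in summaries],
            "mean_delta_tmin": [s.mean_delta for s in summaries],
            "sd_delta_tmin": [s.sd_delta for s in summaries],
            "n": [s.n for s in summaries],
        }
    )


def rmse(A, B) -> float:
    """Root-mean-square difference between two equal-length vectors."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValidationError("rmse needs equal-length vectors")
    return float(np.sqrt(np.mean((A - B) ** 2)))


def pearson(A, B) -> float:
    """Pearson product-moment correlation of two vectors."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.size < 2:
        raise ValidationError("pearson needs equal-length vectors of size >= 2")
    if np.ptp(A) == 0.0 or np.ptp(B) == 0.0:
        raise ValidationError("pearson undefined for constant input")
    return float(stats.pearsonr(A, B).statistic)
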