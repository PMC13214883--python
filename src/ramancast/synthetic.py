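"""Synthetic fermentation-like Raman spectral time series.

Emulates fed-batch yeast runs monitored by an in-line Raman probe: ~90 h
batches, acquisition every hour (or 30 min / 5 min), a 100-3425 cm^-1 axis,
and spectra driven by a small number of smooth latent process trajectories
— a monotone biomass-like latent (logistic) and a bell-shaped metabolite-
like latent (rise to a peak, then decline) — each tied to a fixed pure-
component spectrum built from Gaussian bands. An additive per-hour baseline
drift and i.i.d. Gaussian channel noise complete the observation model:

    spectrum(t) = sum_c latent_c(t) * purespec_c + drift * t + noise

Ground truth (latent values and an OD650-like biomass readout) is returned
alongside each batch so downstream models can be trained and scored.

Two presets matter in practice: ``linear-exact`` (noiseless, latents linear
in time so the second latent is affine in the first — the anticipation
pipeline's model class contains the truth and predictions are exact) and
``realistic-yeast`` (logistic + bell latents, drift, low channel noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .io import SpectraSeries, Spectrum

__all__ = [
    "PeakSpec",
    "LatentConfig",
    "SyntheticConfig",
    "GroundTruth",
    "simulate_batch",
    "simulate_cohort",
    "preset",
    "PRESETS",
]

# Channel noise of the realistic-yeast preset: 1% of the median
# within-window (5 h, hourly) RMS signal variation of the noiseless
# trajectories (0.221), measured once on the preset itself.
_REALISTIC_NOISE_SD = 0.0022


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian Raman band: centre (cm^-1), width (sd, cm^-1), height."""

    center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"peak width must be > 0, got {self.width}")


@dataclass(frozen=True)
class LatentConfig:
    """A latent process trajectory.

    modes: ``linear`` (intercept, slope), ``logistic`` (plateau, rate,
    midpoint_h — biomass-like monotone growth), ``bell`` (amplitude,
    peak_h, spread_h — metabolite-like rise and fall).
    """

    mode: str
    params: tuple = ()

    def __post_init__(self) -> None:
        n_expected = {"linear": 2, "logistic": 3, "bell": 3}
        if self.mode not in n_expected:
            raise ConfigError(f"unknown latent mode {self.mode!r}")
        if len(self.params) != n_expected[self.mode]:
            raise ConfigError(
                f"{self.mode} latent needs {n_expected[self.mode]} parameters"
            )
        if self.mode == "logistic" and (self.params[0] <= 0 or self.params[1] <= 0):
            raise ConfigError("logistic latent needs plateau > 0 and rate > 0")
        if self.mode == "bell" and self.params[2] <= 0:
            raise ConfigError("bell latent needs spread_h > 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.mode == "linear":
            intercept, slope = self.params
            return intercept + slope * t
        if self.mode == "logistic":
            plateau, rate, midpoint = self.params
            return plateau / (1.0 + np.exp(-rate * (t - midpoint)))
        amplitude, peak, spread = self.params
        return amplitude * np.exp(-0.5 * ((t - peak) / spread) ** 2)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level simulation settings (per-batch jitter emulates the
    deliberately varied process parameters of a development campaign)."""

    duration_h: float = 90.0
    interval_h: float = 1.0
    axis_lo: float = 100.0
    axis_hi: float = 3425.0
    axis_step: float = 1.0
    components: tuple = ()  # of (LatentConfig, tuple[PeakSpec, ...] | None)
    baseline_drift: float = 0.0  # additive intensity units per hour
    noise_sd: float = 0.0
    seed: int = 0
    n_batches: int = 23
    batch_jitter: float = 0.0  # relative sd of latent-parameter perturbation
    od_gain: float = 1.0  # OD650-like readout = od_gain * first latent

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.interval_h <= 0 or self.axis_step <= 0:
            raise ConfigError("duration_h, interval_h and axis_step must be > 0")
        if self.noise_sd < 0 or self.batch_jitter < 0:
            raise ConfigError("noise_sd and batch_jitter must be >= 0")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if not self.components:
            raise ConfigError("at least one (latent, peaks) component required")
        if self.od_gain <= 0:
            raise ConfigError("od_gain must be > 0")

    @property
    def axis(self) -> np.ndarray:
        return np.arange(self.axis_lo, self.axis_hi + self.axis_step / 2,
                         self.axis_step)

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + self.interval_h / 2,
                         self.interval_h)


@dataclass
class GroundTruth:
    """Latent trajectories and the OD650-like biomass readout of a batch."""

    times: np.ndarray
    latents: np.ndarray  # (n_times, n_components)
    od: np.ndarray

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"time_h": self.times})
        for c in range(self.latents.shape[1]):
            df[f"latent_{c}"] = self.latents[:, c]
        df["od"] = self.od
        return df


def _pure_spectrum(axis: np.ndarray, peaks) -> np.ndarray:
    out = np.zeros_like(axis)
    for p in peaks:
        out += p.height * np.exp(-0.5 * ((axis - p.center) / p.width) ** 2)
    return out


def _component_peaks(cfg: SyntheticConfig, comp_index: int) -> tuple:
    """Seeded random bands (5-15 Gaussians) for components that do not
    declare explicit peaks; shared across all batches of a cohort."""
    rng = np.random.default_rng([cfg.seed, 1_000_003 + comp_index])
    n = int(rng.integers(5, 16))
    centers = rng.uniform(cfg.axis_lo, cfg.axis_hi, n)
    widths = rng.uniform(8.0, 40.0, n)
    heights = rng.uniform(0.2, 1.0, n)
    return tuple(PeakSpec(c, w, h) for c, w, h in zip(centers, widths, heights))


def _jittered_latent(latent: LatentConfig, jitter: float, rng) -> LatentConfig:
    if jitter == 0.0:
        return latent
    factors = 1.0 + jitter * rng.standard_normal(len(latent.params))
    # keep sign/positivity constraints intact under perturbation
    params = tuple(
        p * max(f, 0.05) if p > 0 else p * f
        for p, f in zip(latent.params, factors)
    )
    return replace(latent, params=params)


def simulate_batch(cfg: SyntheticConfig, batch_index: int = 0):
    """One batch: (SpectraSeries, GroundTruth), deterministic given
    ``(cfg.seed, batch_index)``."""
    rng = np.random.default_rng([cfg.seed, batch_index])
    axis = cfg.axis
    times = cfg.times

    latents = []
    signal = np.zeros((times.size, axis.size))
    for c, (latent, peaks) in enumerate(cfg.components):
        latent = _jittered_latent(latent, cfg.batch_jitter, rng)
        pure = _pure_spectrum(axis, peaks if peaks else _component_peaks(cfg, c))
        z = latent.evaluate(times)
        latents.append(z)
        signal += np.outer(z, pure)
    signal += cfg.baseline_drift * times[:, None]
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, signal.shape)

    spectra = [Spectrum(axis, row, t) for t, row in zip(times, signal)]
    series = SpectraSeries(
        batch_id=f"batch_{batch_index:02d}",
        spectra=spectra,
        nominal_interval_h=cfg.interval_h,
    )
    latents = np.column_stack(latents)
    truth = GroundTruth(times=times, latents=latents,
                        od=cfg.od_gain * latents[:, 0])
    return series, truth


def simulate_cohort(cfg: SyntheticConfig):
    """``cfg.n_batches`` independent batches; latent parameters jittered per
    batch by ``batch_jitter``, noise drawn from per-batch substreams."""
    return [simulate_batch(cfg, b) for b in range(cfg.n_batches)]


def _linear_exact(seed: int, **overrides) -> SyntheticConfig:
    # two latents linear in time => the second is affine in the first and
    # every spectrum lies in a 1-D affine subspace: the anticipation model
    # class contains the truth, predictions are exact at every horizon.
    defaults = dict(
        components=(
            (LatentConfig("linear", (1.0, 0.05)), None),
            (LatentConfig("linear", (2.0, 0.15)), None),
        ),
        baseline_drift=0.0,
        noise_sd=0.0,
        batch_jitter=0.0,
        n_batches=3,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _realistic_yeast(seed: int, **overrides) -> SyntheticConfig:
    defaults = dict(
        components=(
            # biomass-like: logistic to a plateau of 30 (OD-scale units)
            (LatentConfig("logistic", (30.0, 0.12, 40.0)), None),
            # metabolite-like (ethanol): peak near 45 h, then decline
            (LatentConfig("bell", (12.0, 45.0, 12.0)), None),
        ),
        baseline_drift=0.005,
        noise_sd=_REALISTIC_NOISE_SD,
        batch_jitter=0.05,
        n_batches=23,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


PRESETS = {
    "linear-exact": _linear_exact,
    "realistic-yeast": _realistic_yeast,
}


def preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named simulation presets: ``linear-exact`` and ``realistic-yeast``.

    Keyword overrides replace any SyntheticConfig field (e.g.
    ``interval_h=0.5``, ``n_batches=5``).
    """
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return factory(seed, **overrides)
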