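"""Second-derivative (d2) detrending of spectra.

A smoothed second derivative along the channel index removes additive and
linear baseline contributions before spectra are compared or fed to a
chemometrics model. Implemented as a Savitzky-Golay smoothing-derivative
filter; the axis is assumed near-uniform so the filter runs on the channel
index, and boundary points use the filter's polynomial edge fits so the
output stays on the full axis (cosine comparison needs aligned vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.signal import savgol_filter

from .errors import ConfigError, ValidationError
from .io import Spectrum

__all__ = ["DetrendConfig", "d2_detrend"]


@dataclass(frozen=True)
class DetrendConfig:
    """Savitzky-Golay second-derivative settings.

    window_points : odd filter length in channels (>= 5).
    poly_order : local polynomial degree, >= 2 (a second derivative needs at
        least a quadratic) and < window_points.
    """

    window_points: int = 15
    poly_order: int = 3
    derivative_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points < 5 or self.window_points % 2 == 0:
            raise ConfigError(
                f"window_points must be odd and >= 5, got {self.window_points}"
            )
        if not 2 <= self.poly_order < self.window_points:
            raise ConfigError(
                f"poly_order must be in [2, window_points), got {self.poly_order}"
            )
        if self.derivative_order != 2:
            raise ConfigError("only the second derivative is supported")


def d2_detrend(spectrum: Spectrum, cfg: DetrendConfig = DetrendConfig()) -> Spectrum:
    """Smoothed second derivative of a spectrum (same axis, same time).

    Affine ramps in the intensities map to (numerically) zero, so any linear
    baseline added to the input leaves the output unchanged.
    """
    if spectrum.n_channels < cfg.window_points:
        raise ValidationError(
            f"spectrum has {spectrum.n_channels} channels; "
            f"detrending needs >= {cfg.window_points}"
        )
    d2 = savgol_filter(
        spectrum.intensities,
        window_length=cfg.window_points,
        polyorder=cfg.poly_order,
        deriv=cfg.derivative_order,
        delta=1.0,  # per channel-index unit
        mode="interp",
    )
    return Spectrum(spectrum.wavenumbers, d2, spectrum.time_h)
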