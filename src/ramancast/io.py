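"""Time-stamped Raman spectral series: containers, CSV I/O, range restriction.

A batch is stored as a wide CSV — one row per acquisition, ``time_h`` first,
then one column per wavenumber (cm^-1, strictly ascending). This is the
canonical lossless on-disk form for a single fermentation run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Spectrum",
    "SpectraSeries",
    "read_series_csv",
    "write_series_csv",
    "truncate_range",
]


@dataclass
class Spectrum:
    """One Raman acquisition.

    Parameters
    ----------
    wavenumbers : array-like
        Raman shift axis in cm^-1, strictly increasing, finite.
    intensities : array-like
        Scattering intensity per channel, arbitrary units.
    time_h : float
        Hours since culture start (>= 0).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    time_h: float

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.time_h = float(self.time_h)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValidationError(
                f"axis length {self.wavenumbers.size} != intensity length "
                f"{self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise ValidationError("a spectrum needs at least 2 channels")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError("non-finite wavenumber values")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError(f"non-finite intensities at t={self.time_h}")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValidationError("wavenumbers must be strictly increasing")
        if not (self.time_h >= 0):
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size


@dataclass
class SpectraSeries:
    """Time-ordered spectra of one batch, on a shared wavenumber axis."""

    batch_id: str
    spectra: list[Spectrum]
    nominal_interval_h: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        if not self.spectra:
            return  # empty series allowed in memory; writing refuses it
        times = np.array([s.time_h for s in self.spectra])
        if not np.all(np.diff(times) > 0):
            bad = np.flatnonzero(np.diff(times) <= 0)
            raise ValidationError(
                "spectra times must be strictly increasing; offending pairs at "
                f"indices {bad.tolist()} (times {times[bad].tolist()} -> "
                f"{times[bad + 1].tolist()})"
            )
        axis = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.size != axis.size or not np.array_equal(
                s.wavenumbers, axis
            ):
                raise ValidationError(
                    f"spectrum at t={s.time_h} is not on the shared axis"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def axis(self) -> np.ndarray:
        if not self.spectra:
            raise ValidationError("empty series has no axis")
        return self.spectra[0].wavenumbers

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_h for s in self.spectra])

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_channels) stack of intensities in time order."""
        return np.vstack([s.intensities for s in self.spectra])

    def at(self, time_h: float, atol: float = 1e-9) -> Spectrum | None:
        """Spectrum at exactly ``time_h`` (within ``atol``), else None."""
        idx = np.flatnonzero(np.isclose(self.times, time_h, atol=atol, rtol=0.0))
        return self.spectra[int(idx[0])] if idx.size else None

    def last_at_or_before(self, time_h: float) -> Spectrum | None:
        """Most recent spectrum with time_h <= ``time_h`` (floor semantics)."""
        candidates = [s for s in self.spectra if s.time_h <= time_h + 1e-12]
        return candidates[-1] if candidates else None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensity_matrix(), columns=[repr(float(w)) for w in self.axis]
        )
        df.insert(0, "time_h", self.times)
        return df


def read_series_csv(path, batch_id: str | None = None) -> SpectraSeries:
    """Read a wide spectra CSV into a validated :class:`SpectraSeries`.

    The header must start with ``time_h`` followed by strictly ascending
    real wavenumbers. Rows are re-sorted by time; duplicate timestamps are
    rejected (they would make the batch time axis ambiguous).
    """
    try:
        df = pd.read_csv(path, header=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError("need a time_h column plus at least 2 wavenumbers")
    if df.columns[0] != "time_h":
        raise FormatError(
            f"first header cell must be 'time_h', got {df.columns[0]!r}"
        )
    try:
        axis = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from exc
    if not np.all(np.diff(axis) > 0):
        raise FormatError("wavenumber headers must be strictly ascending")
    if df.isna().any().any():
        raise FormatError(f"missing/ragged cells in {path}")

    times = df["time_h"].to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size:
        raise ValidationError(
            f"duplicate time_h values {sorted(set(times[dup].tolist()))} "
            f"in {path}"
        )
    values = df.iloc[:, 1:].to_numpy(dtype=float)[order]
    if batch_id is None:
        batch_id = str(getattr(path, "stem", None) or path)
    spectra = [
        Spectrum(wavenumbers=axis, intensities=row, time_h=t)
        for t, row in zip(times, values)
    ]
    return SpectraSeries(batch_id=batch_id, spectra=spectra)


def write_series_csv(series: SpectraSeries, path) -> None:
    """Write a series as wide CSV; round-trips through :func:`read_series_csv`
    at full floating precision (headers and cells written with ``repr``)."""
    if len(series) == 0:
        raise ValidationError("refusing to write an empty series")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("time_h," + ",".join(repr(float(w)) for w in series.axis) + "\n")
        for s in series:
            fh.write(
                repr(float(s.time_h))
                + ","
                + ",".join(repr(float(v)) for v in s.intensities)
                + "\n"
            )


def truncate_range(series: SpectraSeries, lo: float, hi: float) -> SpectraSeries:
    """Restrict every spectrum to wavenumbers in the closed interval [lo, hi].

    Both endpoints are kept; times and spectrum count are untouched.
    """
    if not lo < hi:
        raise ValidationError(f"need lo < hi, got [{lo}, {hi}]")
    if len(series) == 0:
        return SpectraSeries(series.batch_id, [], series.nominal_interval_h)
    mask = (series.axis >= lo) & (series.axis <= hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"interval [{lo}, {hi}] retains {int(mask.sum())} channel(s); "
            "need at least 2"
        )
    spectra = [
        Spectrum(s.wavenumbers[mask], s.intensities[mask], s.time_h)
        for s in series
    ]
    return SpectraSeries(series.batch_id, spectra, series.nominal_interval_h)
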