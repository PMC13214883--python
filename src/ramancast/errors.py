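"""Exception hierarchy.

The CLI maps these onto exit codes: configuration problems -> 2, data
validation/format problems -> 3, not-enough-data conditions -> 4.
"""


class RamancastError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RamancastError):
    """Invalid or inconsistent configuration."""


class FormatError(RamancastError):
    """Malformed on-disk input (bad header, ragged rows, unparseable cells)."""


class ValidationError(RamancastError):
    """Well-formed input violating a domain invariant."""


class InsufficientDataError(RamancastError):
    """Too few spectra to carry out the requested operation."""


class DegenerateWindowError(InsufficientDataError):
    """Accumulation window with no spectral variance (all spectra identical)."""


class DegeneratePredictorError(RamancastError):
    """Trend fit requested against a constant predictor."""


class UndefinedSimilarityError(ValidationError):
    """Cosine similarity requested for a zero-norm vector."""
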