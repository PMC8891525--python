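"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`NeurotauError` so callers (and the
CLI) can distinguish user-input problems from genuine bugs.
"""


class NeurotauError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(NeurotauError):
    """Two volumes do not share shape and affine."""


class DataError(NeurotauError):
    """Input data violate a contract (non-finite values, negative durations...)."""


class SchemaError(NeurotauError):
    """A tabular input is malformed (missing columns, duplicate ids)."""


class DegenerateSignalError(NeurotauError):
    """A time series or map carries no usable variance."""


class BandError(NeurotauError):
    """A spectral band lies outside (0, Nyquist]."""


class InfeasibleThresholdError(NeurotauError):
    """A Bonferroni-corrected correlation threshold is numerically >= 1."""


class DesignError(NeurotauError):
    """A design matrix is rank deficient or otherwise unusable."""


class CollinearityError(DesignError):
    """Predictors are linearly dependent; names of offending columns attached."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientDataError(NeurotauError):
    """Too few units (voxels, parcels, subjects) to run the requested analysis."""


class ConfigError(NeurotauError):
    """A configuration value violates its declared invariant."""
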