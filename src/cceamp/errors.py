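"""Exception hierarchy for validation failures.

All errors raised for bad inputs derive from :class:`CceampError`, itself a
``ValueError``, so callers can catch one type at the CLI boundary.
"""


class CceampError(ValueError):
    """Base class for all input-validation errors raised by cceamp."""


class InsufficientCurveError(CceampError):
    """Standard curve has fewer than three distinct dilution levels."""


class InvertedSeriesError(CceampError):
    """Dilution series slope is non-negative (Cq must rise as template falls)."""


class InvalidEfficiencyError(CceampError):
    """Amplification efficiency outside the plausible (1.0, 2.2] range."""


class NoReferenceError(CceampError):
    """No reference-gene fold available for normalization."""


class UnquantifiableSampleError(CceampError):
    """Sample lacks any determined Cq for every reference gene."""


class FailedWellError(CceampError):
    """Duplex well with undetermined control (HEX) signal."""


class InvalidThresholdError(CceampError):
    """Fluorescence threshold at or below baseline noise."""


class SaturationError(CceampError):
    """Every droplet positive: template too concentrated to quantify."""


class EmptyWellError(CceampError):
    """Droplet well with zero total droplets."""


class NoControlSignalError(CceampError):
    """Control-gene ddPCR well with zero estimated concentration."""


class EmptyPopulationError(CceampError):
    """Population summary requested for an empty call list."""


class GridMismatchError(CceampError):
    """Two depth tracks do not share an identical window grid."""


class BedParseError(CceampError):
    """Malformed BED/BedGraph record; message carries the line number."""


class TableFormatError(CceampError):
    """Delimited table missing required columns or containing duplicates."""
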