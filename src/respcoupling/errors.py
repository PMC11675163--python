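"""Exception hierarchy for respcoupling.

All package-raised errors derive from :class:`RespCouplingError` so the
pipeline can distinguish a per-subject analysis failure (skip and warn)
from a programming error (propagate).
"""


class RespCouplingError(Exception):
    """Base class for all errors raised by respcoupling."""


class TraceFormatError(RespCouplingError):
    """A trace file is malformed (e.g. a configured column is missing)."""


class TraceParseError(RespCouplingError):
    """A trace file contains a non-numeric or non-finite cell."""


class SamplingRateError(RespCouplingError):
    """A time column's spacing disagrees with the declared sampling rate."""


class TraceLengthError(RespCouplingError):
    """A trace is too short for the requested operation."""


class DegenerateSignalError(RespCouplingError):
    """A signal is constant (or all-zero) where variation is required."""


class ConfigError(RespCouplingError):
    """Invalid configuration value (band edges, delays, windows, ...)."""


class PairingError(RespCouplingError):
    """Two traces or fits that must match in length/rate/subject do not."""


class RankError(RespCouplingError):
    """The regression design matrix is rank deficient."""


class SummaryError(RespCouplingError):
    """Too few (usable) subjects to form a cohort summary."""
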