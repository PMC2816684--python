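"""Exception types shared across the package.

All validation errors identify the offending record(s); readers reject
rather than repair.
"""


class MethylEraseError(Exception):
    """Base class for package errors."""


class TrackValidationError(MethylEraseError):
    """A nucleosome annotation track violates an invariant (the message names the record)."""


class MatrixValidationError(MethylEraseError):
    """A time-course matrix violates an invariant (duplicate ids, non-monotone times, ...)."""


class DegenerateLocusError(MethylEraseError):
    """A locus reached a state where the measurement model is undefined (M == 0)."""


class CalibrationError(MethylEraseError):
    """Rate calibration could not bracket or reach the requested target."""
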