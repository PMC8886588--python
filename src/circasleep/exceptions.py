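"""Exception hierarchy for data and numerical failures."""


class CircasleepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CircasleepError, ValueError):
    """A file could not be parsed (bad timestamps, wrong columns)."""


class DataError(CircasleepError, ValueError):
    """Parsed data violate a structural requirement (duplicates, overlaps)."""


class InsufficientDataError(CircasleepError, ValueError):
    """Too little data to compute the requested quantity."""


class DegenerateSignalError(CircasleepError, ValueError):
    """Signal has zero variance; period estimation is undefined."""


class PeriodRangeError(CircasleepError, ValueError):
    """Requested candidate-period range is outside the estimable window."""


class NumericalError(CircasleepError, RuntimeError):
    """Integration produced non-finite state."""
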