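"""Exception hierarchy for the mhnet pipeline.

Every error raised on bad user input derives from :class:`ValidationError`
so the CLI can map it to exit code 2; unexpected runtime failures propagate
as ordinary exceptions (exit code 1).
"""


class MhnetError(Exception):
    """Base class for all package errors."""


class ValidationError(MhnetError, ValueError):
    """Invalid input data or configuration."""


class PanelFormatError(ValidationError):
    """A CSV is missing required columns or has unparseable values."""


class PanelIntegrityError(ValidationError):
    """Duplicate (date, state) cells or inconsistent panel structure."""


class GapTooLargeError(ValidationError):
    """A run of missing unit-days exceeds the allowed interpolation span."""


class ConstantSeriesError(ValidationError):
    """Pearson correlation is undefined for a zero-variance series."""


class GroupingError(ValidationError):
    """A grouping scheme does not cover the units or has degenerate groups."""
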