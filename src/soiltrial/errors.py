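"""Exception hierarchy shared across the package.

Every error raised on user data derives from :class:`SoilTrialError` so
callers (and the CLI) can distinguish domain failures from programming
errors and map them to stable exit codes.
"""


class SoilTrialError(Exception):
    """Base class for all domain errors."""

    exit_code = 1


class SchemaError(SoilTrialError):
    """A table is missing required columns or has an unusable header."""

    exit_code = 2


class ValidationError(SoilTrialError):
    """A row violates a domain invariant (range, uniqueness, unknown code)."""

    exit_code = 3


class ConfigError(SoilTrialError):
    """A configuration value is out of its allowed domain."""

    exit_code = 4


class DegenerateDataError(SoilTrialError):
    """The data are formally valid but the requested statistic is undefined
    on them (constant indicator, all-zero yield series, single year)."""

    exit_code = 5


class AlignmentError(SoilTrialError):
    """Two aligned structures (scores vs weights) disagree on their labels."""

    exit_code = 6


class StageError(SoilTrialError):
    """A pipeline stage cannot run because an upstream artifact is absent."""

    exit_code = 7
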