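"""Exception hierarchy for gaseg.

Every error raised deliberately by the package derives from :class:`GasegError`
so callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class GasegError(Exception):
    """Base class for all gaseg errors."""


class FormatError(GasegError):
    """A file could not be read in the expected on-disk format."""


class CorruptStackError(FormatError):
    """Pages of a multi-page volume disagree in size."""


class SchemaError(GasegError):
    """A metadata table is missing required columns."""


class IntegrityError(GasegError):
    """A cohort-level consistency rule is violated (e.g. duplicate scan keys)."""


class ShapeError(GasegError):
    """Array dimensions do not match the operation's contract."""


class ConfigError(GasegError):
    """An invalid or inconsistent configuration value."""


class CapabilityError(GasegError):
    """An operation was requested for a device that does not support it."""


class ParameterError(GasegError):
    """A synthetic-generation parameter is out of its valid range."""


class InsufficientDataError(GasegError):
    """Too few observations for the requested statistic."""


class TrainingDivergedError(GasegError):
    """The optimization produced a non-finite loss."""
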