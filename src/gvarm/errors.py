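"""Exception hierarchy for gvarm."""


class GvarmError(Exception):
    """Base class for all gvarm errors."""


class ConfigError(GvarmError, ValueError):
    """A configuration value is invalid; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FormatError(GvarmError, ValueError):
    """An input file does not conform to the expected dialect."""


class EmptyInputError(GvarmError, ValueError):
    """An operation received no usable data."""


class UndefinedStatisticError(GvarmError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
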