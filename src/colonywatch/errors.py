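"""Exception hierarchy shared by all pipeline stages."""


class ColonywatchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ColonywatchError):
    """Invalid configuration or simulation-truth field; names the field."""


class DataError(ColonywatchError):
    """Malformed input data; names file/row/column where possible."""


class DomainError(ColonywatchError):
    """Argument outside the mathematical domain of an operation."""


class DegenerateGroupError(ColonywatchError):
    """A standardization group has zero spread or too few values."""


class UndefinedMetricError(ColonywatchError):
    """An occupancy metric has an empty denominator."""


class ComparabilityError(ColonywatchError):
    """Model candidates were fitted on different data rows."""
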