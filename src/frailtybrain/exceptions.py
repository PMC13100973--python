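"""Exception hierarchy shared across the package."""


class FrailtyBrainError(Exception):
    """Base class for package errors."""


class ConfigurationError(FrailtyBrainError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class SchemaError(FrailtyBrainError, KeyError):
    """Input table does not match the expected column schema."""


class CollinearityError(FrailtyBrainError, ValueError):
    """Design matrix is rank deficient; the message names the collinear columns."""


class DegenerateDataError(FrailtyBrainError, ValueError):
    """Data admit no valid estimate (e.g. zero variance, empty retained set)."""
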