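"""Exception hierarchy shared across the package."""


class BeatchirpError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BeatchirpError, ValueError):
    """A stimulus/model parameter is invalid; the message names the field."""


class InputError(BeatchirpError, ValueError):
    """Input data to an analysis operation are unusable."""


class ConfigurationError(BeatchirpError, ValueError):
    """A run configuration is inconsistent (e.g. <2 afferents for a correlation run)."""


class UndefinedMetricError(BeatchirpError, ArithmeticError):
    """A scalar metric is mathematically undefined for these inputs.

    Raised instead of returning a sentinel so that an undefined phase-locking
    index or distance can never be confused with a legitimate 0 or 1.
    """
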