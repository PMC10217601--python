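"""Exception types shared across the package."""


class NfmoError(Exception):
    """Base class for all package errors."""


class ValidationError(NfmoError, ValueError):
    """An argument violates a documented contract (shape, dtype, range)."""


class FormatError(NfmoError, ValueError):
    """An image file cannot be read or written in a supported form."""


class ConfigurationError(NfmoError, ValueError):
    """A configuration artefact (kernel override file, config file) is invalid."""


class UndefinedMetricError(NfmoError, ArithmeticError):
    """A metric is mathematically undefined for the given inputs
    (e.g. the colour-difference ratio on an all-black reference image)."""
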