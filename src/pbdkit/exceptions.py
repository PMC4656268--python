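"""Exception hierarchy shared across pbdkit modules."""


class PBDKitError(Exception):
    """Base class for all pbdkit errors."""


class ConfigurationError(PBDKitError, ValueError):
    """An option names something unknown or inconsistent (wavelet, kernel, mode...)."""


class ValidationError(PBDKitError, ValueError):
    """Input data violates a documented precondition."""


class SizeError(ValidationError):
    """Input too small for the requested decomposition depth."""


class ConvergenceError(PBDKitError, RuntimeError):
    """The dual solver failed to reach its KKT tolerance within the iteration budget."""
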