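"""Exception hierarchy shared across the package."""


class QpiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(QpiError, ValueError):
    """An input array or domain object violates its invariants."""


class ParameterError(QpiError, ValueError):
    """A scalar parameter is outside its admissible range."""


class CarrierDetectionError(QpiError, RuntimeError):
    """No off-axis carrier peak could be located in the hologram spectrum."""


class SpecRejectionError(QpiError, ValueError):
    """A phantom specification produces a physically invalid (negative) thickness."""
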