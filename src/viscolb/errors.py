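"""Exception types shared across the solver."""


class ViscolbError(Exception):
    """Base class for all viscolb errors."""


class ConfigurationError(ViscolbError):
    """Invalid or inconsistent simulation configuration."""


class InvalidStateError(ViscolbError):
    """A field violates a physical invariant (e.g. non-positive density)."""


class NumericalBlowupError(ViscolbError):
    """NaN/Inf detected in a population field."""

    def __init__(self, message, node=None):
        super().__init__(message)
        self.node = node


class StabilityError(ViscolbError):
    """A stability limit was exceeded (CFL, relaxation-time bounds, ...)."""


class SubsonicWarning(UserWarning):
    """Velocity magnitude approaching the lattice validity limit."""
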