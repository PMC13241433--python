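"""Exception types shared across the package."""


class PoroarteryError(Exception):
    """Base class for all package errors."""


class InvalidDeformationError(PoroarteryError):
    """A kinematic denominator (1 - dus/dr or 1 - us/r) is non-positive."""


class PorosityBoundError(PoroarteryError):
    """The fluid volume fraction left the open interval (0, 1)."""


class ConvergenceError(PoroarteryError):
    """Newton iteration or pressure continuation failed."""

    def __init__(self, message, dp_mmhg=None):
        super().__init__(message)
        self.dp_mmhg = dp_mmhg


class ConfigError(PoroarteryError):
    """Invalid or inconsistent run configuration."""
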