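"""Exception hierarchy shared across the package."""


class LambdahopError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(LambdahopError):
    """A configuration violates its invariants (non-finite or mis-shaped)."""


class InvalidSystemError(LambdahopError):
    """System parameters violate their invariants."""


class ProtocolError(LambdahopError):
    """A ladder / scaling-protocol argument is out of range."""


class CalibrationError(LambdahopError):
    """Root-finding for a calibration target failed to converge."""


class DiagnosticsError(LambdahopError):
    """A diagnostics quantity is undefined for the given trace/samples."""


class EstimatorError(LambdahopError):
    """A free-energy estimator failed or was given invalid input."""
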