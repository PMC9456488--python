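"""Exception hierarchy shared across the pipeline stages."""


class EcgRobustError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EcgRobustError, ValueError):
    """A caller-supplied argument violates a precondition."""


class DegenerateSignalError(EcgRobustError, ValueError):
    """The signal is degenerate for the requested operation.

    Raised e.g. for min-max normalization of a constant trace
    (x_max == x_min) or SNR mixing into a zero-power signal.
    """


class InsufficientLengthError(EcgRobustError, ValueError):
    """The series is too short for the requested embedding/filter."""


class InvalidStateError(EcgRobustError, RuntimeError):
    """An operation was invoked before its prerequisites (e.g. training)."""
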