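"""Exception and warning types shared across the package."""


class CanineTraceError(Exception):
    """Base class for all errors raised by canine_trace."""


class ValidationError(CanineTraceError):
    """An input violates a documented invariant (bad mesh, bad transform, bad score)."""


class MeshFormatError(CanineTraceError):
    """An STL file could not be parsed.

    Carries ``byte_offset``, the position in the file where parsing failed
    (or where the size/record-count mismatch was detected).
    """

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class InsufficientLandmarksError(ValidationError):
    """Fewer than three landmarks supplied to a rigid fit."""


class CorrespondenceError(ValidationError):
    """Two landmark sets are not paired (name sequences differ)."""


class DegenerateConfigurationError(ValidationError):
    """Landmark configuration is collinear: the rigid fit is under-determined."""


class MethodUnavailableError(CanineTraceError):
    """A measurement method cannot run on this case (e.g. no final CBCT)."""


class PipelineError(CanineTraceError):
    """A step of the five-step intraoral-scan pipeline could not run.

    ``step`` is the 1-based step number of the protocol diagram.
    """

    def __init__(self, message: str, step: int):
        super().__init__(f"step {step}: {message}")
        self.step = step


class RegistrationWarning(UserWarning):
    """Non-fatal registration concern (e.g. fewer skull points than recommended)."""


class ConvergenceWarning(UserWarning):
    """Iterative refinement stopped at the iteration cap without meeting tolerance."""
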