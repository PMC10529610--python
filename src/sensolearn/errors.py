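"""Exceptions shared across the pipeline stages."""


class SensolearnError(Exception):
    """Base class for package errors."""


class SimulationError(SensolearnError):
    """Raised when a forward simulation produces a non-finite update.

    Carries the trial index at which the generative trajectory broke down.
    """

    def __init__(self, message: str, trial: int | None = None):
        super().__init__(message)
        self.trial = trial


class ModelDivergenceError(SensolearnError):
    """Raised when a filter trajectory becomes invalid (non-positive
    variance or non-finite state).  The inverter treats this as a rejected
    parameter proposal, never as a crash."""

    def __init__(self, message: str, trial: int | None = None):
        super().__init__(message)
        self.trial = trial


class PreprocessingError(SensolearnError):
    """Raised for signals that cannot be preprocessed (too short for the
    filter warm-up, zero variance where a z-score is required, ...)."""


class ValidationError(SensolearnError):
    """Raised when an imported table or configuration fails validation."""
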