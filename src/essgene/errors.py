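"""Exception hierarchy shared across the package."""


class EssgeneError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EssgeneError):
    """A record or argument violates an operation's preconditions."""


class ConfigurationError(EssgeneError):
    """A configuration value is unknown or inconsistent."""


class StateError(EssgeneError):
    """An object was used before being put in the required state."""


class TrainingFailureError(EssgeneError):
    """Optimization produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
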