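"""Exception hierarchy shared across the pipeline stages."""


class FnirsTransferError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FnirsTransferError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(FnirsTransferError, ValueError):
    """A configuration object is internally inconsistent (e.g. singular
    extinction matrix, empty subject group)."""


class ShapeError(FnirsTransferError, ValueError):
    """Layer-shape arithmetic produced a non-integer or non-positive size."""

    def __init__(self, message: str, layer_index: int | None = None):
        super().__init__(message)
        self.layer_index = layer_index


class TrainingError(FnirsTransferError, RuntimeError):
    """Training diverged or was called with no trainable parameters."""


class EmptyEpochsError(FnirsTransferError, ValueError):
    """Windowing produced no examples (window longer than every segment)."""


class IntegrityError(FnirsTransferError, RuntimeError):
    """A packaged fixture or serialized artifact failed its checksum."""
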