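"""Labeled error types raised across the package."""


class CadSkinError(Exception):
    """Base class for all package errors."""


class ConfigError(CadSkinError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class DataError(CadSkinError, ValueError):
    """Invalid dataset, image, or label input."""


class ShapeError(CadSkinError, ValueError):
    """Array shape or dimension mismatch."""


class TrainingError(CadSkinError, RuntimeError):
    """Non-finite loss or other failure during optimisation."""

    def __init__(self, message: str, step: int | None = None):
        if step is not None:
            message = f"{message} (step {step})"
        super().__init__(message)
        self.step = step
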