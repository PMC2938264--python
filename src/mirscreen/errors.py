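"""Exception hierarchy shared across the pipeline stages."""


class MirscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirscreenError, ValueError):
    """An invalid generator, fold or pipeline configuration."""


class CalibrationError(MirscreenError, RuntimeError):
    """Noise calibration failed to reach its targets; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(MirscreenError, ValueError):
    """On-disk or in-memory data does not match the expected schema."""


class InsufficientDataError(MirscreenError, ValueError):
    """Too few samples (or groups) for the requested computation."""


class AlreadyCorrectedError(MirscreenError, RuntimeError):
    """Background correction applied twice; the operation is not idempotent."""


class UndefinedValueError(MirscreenError, ValueError):
    """A quantity (ROC, PPV/NPV) is undefined for the given inputs."""


class FoldDegeneracyError(MirscreenError, RuntimeError):
    """A cross-validation training fold contained a single class."""
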