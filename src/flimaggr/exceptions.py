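"""Exception hierarchy shared by all stages."""


class FlimAggrError(Exception):
    """Base class for every error raised by this package."""


class InvalidParameterError(FlimAggrError, ValueError):
    """A parameter violates its stated precondition (non-positive lifetime, ...)."""


class InvalidInputError(FlimAggrError, ValueError):
    """Input data are unusable (empty histogram, non-positive amplitude, ...)."""


class IncompatibleInputError(FlimAggrError, ValueError):
    """Two inputs that must share binning/shape do not."""


class GenerationError(FlimAggrError, RuntimeError):
    """A synthetic scene could not be realised (e.g. a punctum does not fit)."""

    def __init__(self, message: str, cell_label: int | None = None):
        super().__init__(message)
        self.cell_label = cell_label


class FitFailureError(FlimAggrError, RuntimeError):
    """An optimiser failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class InsufficientDataError(FlimAggrError, ValueError):
    """Too few usable points for the requested fit."""


class FormatError(FlimAggrError, ValueError):
    """A file on disk does not match its declared format contract."""


class ConfigError(FlimAggrError, ValueError):
    """A run configuration failed schema validation; message names the field."""
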