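"""Exception hierarchy shared across the pipeline stages."""


class FrcscapeError(Exception):
    """Base class for all package errors."""


class ParameterError(FrcscapeError, ValueError):
    """An invalid parameter value (non-positive size, bad range, ...)."""


class FormatError(FrcscapeError, ValueError):
    """A file does not match the expected on-disk layout."""


class SchemaError(FrcscapeError, ValueError):
    """A table is missing required columns."""


class ValidationError(FrcscapeError, ValueError):
    """Record-level validation failure (duplicate ids, negative times, ...)."""


class PanelError(FrcscapeError, KeyError):
    """A required marker is absent from the panel."""


class DegenerateInputError(FrcscapeError, ValueError):
    """Input is structurally valid but empty/degenerate for this operation."""


class PlacementError(FrcscapeError, RuntimeError):
    """Synthetic cell placement could not satisfy spatial constraints."""
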