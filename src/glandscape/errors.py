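"""Exception hierarchy shared across the pipeline stages."""


class GlandscapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GlandscapeError):
    """A file does not conform to the expected dialect (names the offending line/entry)."""


class ConfigurationError(GlandscapeError):
    """Invalid or inconsistent run configuration."""


class QCConflictError(GlandscapeError):
    """A positive-control well falls below the control-derived QC threshold."""


class EmptyResultError(GlandscapeError):
    """An operation produced an empty result where at least one item is required."""


class DegenerateCellError(GlandscapeError):
    """A cell shares no positive genes with the normalization reference."""


class UnitError(GlandscapeError):
    """An expression matrix carries the wrong unit for the requested operation."""


class FitError(GlandscapeError):
    """Too few usable spike-ins (or otherwise degenerate data) for a model fit."""


class StateError(GlandscapeError):
    """An operation was invoked on an object in an invalid state (e.g. unfitted model)."""
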