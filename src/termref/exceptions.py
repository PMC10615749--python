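"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`TermRefError` so the CLI can map
failure families to distinct exit codes.
"""


class TermRefError(Exception):
    """Base class for all package errors."""


class ValidationError(TermRefError, ValueError):
    """An input value violates a documented precondition."""


class SchemaError(TermRefError):
    """A tabular input is missing required columns or has untypable values."""


class InsufficientDataError(TermRefError):
    """Too few observations to estimate the requested quantity."""


class DegenerateVarianceError(TermRefError):
    """Zero spread in reference scores: severity bands are undefined."""


class EstimationError(TermRefError):
    """Model estimation failed (separation, non-ordered thresholds, ...)."""


class ConfigurationError(TermRefError):
    """A run configuration is inconsistent or references missing files."""
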