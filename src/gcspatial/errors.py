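"""Exception hierarchy shared across the package."""


class GCSpatialError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GCSpatialError):
    """A table is missing required columns or has the wrong shape."""


class ValidationError(GCSpatialError):
    """Row-level contract violations; carries all offending rows."""

    def __init__(self, message: str, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []


class ConfigurationError(GCSpatialError):
    """An operation was asked to run with an inconsistent configuration."""


class InsufficientDataError(GCSpatialError):
    """Too few observations for the requested statistic."""


class InfeasibleError(GCSpatialError):
    """A point-process constraint (e.g. hard-core packing) cannot be satisfied."""
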