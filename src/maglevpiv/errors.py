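"""Package-wide exception types."""


class MaglevPivError(Exception):
    """Base class for all package errors."""


class ConfigError(MaglevPivError):
    """Invalid or incomplete configuration."""


class DegenerateGeometryError(MaglevPivError):
    """Geometry admits no unique solution (e.g. channel parallel to laser)."""


class MeasurementInconsistencyError(MaglevPivError):
    """An observation is inconsistent with the channel geometry."""


class InsufficientDataError(MaglevPivError):
    """Too few observations to perform the requested fit."""
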