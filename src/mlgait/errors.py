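"""Exception hierarchy shared across the toolkit."""


class MlgaitError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(MlgaitError):
    """Invalid configuration or parameters."""


class DataError(MlgaitError):
    """Invalid or inconsistent input data."""


class MissingDataError(DataError):
    """An operation requires gap-free data but missing samples are present."""


class BehindCameraError(DataError):
    """A world point has non-positive depth in the camera frame."""


class InsufficientViewsError(DataError):
    """Fewer than the required number of distinct camera views."""


class DegenerateGeometryError(DataError):
    """Triangulation geometry carries no parallax (e.g. coincident cameras)."""
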