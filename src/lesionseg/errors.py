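"""Exception hierarchy for the package."""


class LesionSegError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(LesionSegError):
    """A configuration object violates its invariants."""


class GeometryError(LesionSegError):
    """Two volumes/masks that must share a voxel grid do not."""


class DegenerateImageError(LesionSegError):
    """An image is degenerate for the requested operation (e.g. zero variance)."""


class UndefinedMetricError(LesionSegError):
    """A metric is undefined for the given input (e.g. empty mask)."""


class PlacementError(LesionSegError):
    """A mask defect could not be placed without violating its contract."""
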