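"""Exception hierarchy for the lcseg package."""


class LcsegError(Exception):
    """Base class for all lcseg-specific errors."""


class FormatError(LcsegError):
    """Input file or array does not meet the expected format."""


class GeometryError(LcsegError):
    """Requested geometry cannot be realized (e.g. structure exceeds grid)."""


class DegenerateGeometryError(GeometryError):
    """Mask geometry is too degenerate for a stable estimate."""


class NormalizationError(LcsegError):
    """Intensity normalization is undefined (e.g. constant patch)."""


class FeatureError(LcsegError):
    """Feature extraction precondition violated (e.g. empty mask)."""


class PlacementError(LcsegError):
    """Reference region cannot be placed on the grid."""


class LocalizationError(LcsegError):
    """Localization stage failed to produce usable candidates."""


class TrainingError(LcsegError):
    """Network training failed (e.g. NaN loss)."""


class EvaluationError(LcsegError):
    """Evaluation metric undefined for the given inputs."""
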