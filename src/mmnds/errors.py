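"""Exception hierarchy shared across the pipeline stages."""


class MMNDSError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MMNDSError, ValueError):
    """A numeric parameter is outside its valid range."""


class GridCompatibilityError(MMNDSError, ValueError):
    """Two volumes do not live on the same voxel grid."""


class EmptyMaskError(MMNDSError, ValueError):
    """A mask construction produced no voxels."""


class UndefinedMeanError(MMNDSError, ValueError):
    """A masked mean has no included voxels."""


class QuantificationError(MMNDSError, ValueError):
    """A normalization reference is zero/negative or otherwise unusable."""


class CatalogError(MMNDSError, KeyError):
    """An ROI name or entity is not present in the catalog."""


class InsufficientDataError(MMNDSError, ValueError):
    """Too few subjects/samples for the requested statistic."""


class MissingValueError(MMNDSError, ValueError):
    """An ROI feature could not be computed (e.g. no voxel passes FA > 0.2)."""


class DegenerateTrainingError(MMNDSError, ValueError):
    """Classifier training received a single class."""


class ConstraintInfeasibleError(MMNDSError, ValueError):
    """Specificity target unreachable under the sensitivity constraint.

    Carries the best attainable (specificity, sensitivity) pair so callers
    can fall back to the best-effort operating point.
    """

    def __init__(self, message: str, best_specificity: float, best_sensitivity: float,
                 best_bias: float):
        super().__init__(message)
        self.best_specificity = best_specificity
        self.best_sensitivity = best_sensitivity
        self.best_bias = best_bias
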