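"""Exception hierarchy for suvkit."""


class SuvkitError(Exception):
    """Base class for all suvkit errors."""


class UnitError(SuvkitError, ValueError):
    """A volume carried the wrong unit tag for an operation."""


class DegenerateInputError(SuvkitError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero counts, empty union)."""


class EmptySegmentationError(SuvkitError, ValueError):
    """Seed voxel does not pass the segmentation threshold."""


class VolumeMatchError(SuvkitError, RuntimeError):
    """No threshold yields a volume within the allowed relative mismatch.

    Attributes
    ----------
    best_mismatch : float
        Smallest achieved |V - target| / target over the searched thresholds.
    """

    def __init__(self, message: str, best_mismatch: float):
        super().__init__(message)
        self.best_mismatch = float(best_mismatch)


class GenerationError(SuvkitError, RuntimeError):
    """Phantom/cohort generation failed (e.g. infeasible lesion packing)."""
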