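"""Threshold-based lesion VOIs and cross-modality volume matching.

A lesion VOI is the 26-connected component of strictly-above-threshold voxels
that contains a seed voxel. Volume matching searches the sorted unique voxel
values of the image below the seed value for the threshold whose component
volume is closest to a target; volume is a non-increasing step function of
the threshold, so a binary search over unique values finds the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptySegmentationError, VolumeMatchError
from .image_model import QuantVolume

__all__ = ["SITES", "LesionVOI", "segment_threshold", "match_volume_threshold", "voi_volume"]

SITES = ("skull", "spine", "rib_cage", "pelvis", "limbs")
LESION_CLASSES = ("metastatic", "benign", "unknown")

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionVOI:
    """An explicit voxel-index set on a named grid with its defining threshold.

    ``indices`` is an (n, 3) integer array of 0-based voxel indices; geometry
    is computed in physical mm from ``spacing``.
    """

    indices: np.ndarray
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    threshold: float
    site: str = "unknown"
    lesion_class: str = "unknown"
    achieved_mismatch: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp).reshape(-1, 3)
        if self.indices.shape[0] == 0:
            raise ValueError("VOI must contain at least one voxel")
        if np.any(self.indices < 0) or np.any(self.indices >= np.array(self.grid_shape)):
            raise ValueError("VOI voxel indices outside grid bounds")

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])

    @property
    def volume_cm3(self) -> float:
        return voi_volume(self, self.spacing)

    def mask(self) -> np.ndarray:
        """Boolean mask of the VOI on its grid."""
        m = np.zeros(self.grid_shape, dtype=bool)
        m[tuple(self.indices.T)] = True
        return m

    def index_set(self) -> set[tuple[int, int, int]]:
        return {tuple(int(v) for v in row) for row in self.indices}


def voi_volume(voi: LesionVOI, spacing: tuple[float, float, float]) -> float:
    """Physical VOI volume in cm^3 = voxel count x voxel volume (mm^3) / 1000."""
    return voi.indices.shape[0] * float(np.prod(spacing)) / 1000.0


def _component_mask(values: np.ndarray, seed: tuple[int, int, int], threshold: float) -> np.ndarray:
    """26-connected component of ``{values > threshold}`` containing ``seed``."""
    above = values > threshold
    labels, _ = ndimage.label(above, structure=_CONN26)
    return labels == labels[seed]


def _check_seed(volume: QuantVolume, seed) -> tuple[int, int, int]:
    seed = tuple(int(v) for v in seed)
    if len(seed) != 3:
        raise ValueError(f"seed must be a 3-tuple, got {seed}")
    if any(s < 0 or s >= n for s, n in zip(seed, volume.shape)):
        raise ValueError(f"seed {seed} out of bounds for shape {volume.shape}")
    return seed


def segment_threshold(
    suv_volume: QuantVolume,
    seed: tuple[int, int, int],
    threshold: float,
    site: str = "unknown",
    lesion_class: str = "unknown",
) -> LesionVOI:
    """Segment the lesion containing ``seed`` as the 26-connected component of
    voxels with value strictly above ``threshold``.
    """
    if suv_volume.unit != "SUV":
        raise ValueError(f"segmentation expects an SUV volume, got {suv_volume.unit}")
    seed = _check_seed(suv_volume, seed)
    if not suv_volume.values[seed] > threshold:
        raise EmptySegmentationError(
            f"seed voxel value {suv_volume.values[seed]:.4g} does not exceed "
            f"threshold {threshold:.4g}"
        )
    mask = _component_mask(suv_volume.values, seed, threshold)
    return LesionVOI(
        np.argwhere(mask), suv_volume.shape, suv_volume.spacing, float(threshold),
        site=site, lesion_class=lesion_class,
    )


def match_volume_threshold(
    suv_volume: QuantVolume,
    seed: tuple[int, int, int],
    target_volume_cm3: float,
    max_rel_mismatch: float = 0.20,
    site: str = "unknown",
    lesion_class: str = "unknown",
) -> LesionVOI:
    """Find the threshold whose seed component volume is closest to a target.

    Candidate thresholds are the sorted unique voxel values strictly below the
    seed value (so the seed always passes). Component volume is non-increasing
    in the threshold, so a binary search brackets the target; ties in |dV| are
    broken toward the larger volume (lower threshold). Raises
    :class:`VolumeMatchError` if the best achievable relative mismatch exceeds
    ``max_rel_mismatch``.
    """
    if target_volume_cm3 <= 0:
        raise ValueError("target volume must be positive")
    seed = _check_seed(suv_volume, seed)
    values = suv_volume.values
    seed_value = values[seed]
    candidates = np.unique(values[values < seed_value])
    if candidates.size == 0:
        raise EmptySegmentationError(
            "no voxel value below the seed value: cannot form a threshold VOI"
        )
    vox_cm3 = suv_volume.voxel_volume_mm3 / 1000.0
    target_n = target_volume_cm3 / vox_cm3

    def component_count(t: float) -> int:
        return int(_component_mask(values, seed, t).sum())

    # component_count is non-increasing over ascending candidate thresholds;
    # find the last candidate whose volume is still >= target.
    lo, hi = 0, candidates.size - 1
    if component_count(candidates[0]) < target_n:
        boundary = -1  # even the most permissive threshold is below target
    elif component_count(candidates[hi]) >= target_n:
        boundary = hi
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if component_count(candidates[mid]) >= target_n:
                lo = mid
            else:
                hi = mid
        boundary = lo

    best_t, best_err, best_n = None, np.inf, 0
    for i in (boundary, boundary + 1):
        if 0 <= i < candidates.size:
            n = component_count(candidates[i])
            err = abs(n - target_n)
            # tie toward the larger volume, i.e. the lower threshold (smaller i)
            if err < best_err - 1e-12:
                best_t, best_err, best_n = candidates[i], err, n
    mismatch = best_err * vox_cm3 / target_volume_cm3
    if mismatch > max_rel_mismatch:
        raise VolumeMatchError(
            f"best achievable volume mismatch {mismatch:.1%} exceeds "
            f"allowed {max_rel_mismatch:.1%} (target {target_volume_cm3:.3g} cm^3, "
            f"closest {best_n * vox_cm3:.3g} cm^3)",
            best_mismatch=mismatch,
        )
    mask = _component_mask(values, seed, best_t)
    voi = LesionVOI(
        np.argwhere(mask), suv_volume.shape, suv_volume.spacing, float(best_t),
        site=site, lesion_class=lesion_class, achieved_mismatch=float(mismatch),
    )
    return voi
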