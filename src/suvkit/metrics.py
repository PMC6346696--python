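"""Per-lesion uptake metrics: SUV_max, SUV_peak, SUV_mean, background SUV, SUVR.

SUV_peak is the maximal mean over ~1-cm^3 cubes whose center voxel lies in
the lesion VOI. The cube edge along each axis is the nearest integer number
of voxels to 10 mm (minimum 1), so the physical cube volume is only
approximately 1 cm^3 and depends on the grid. Cubes may extend outside the
VOI (and are clipped at image borders), which can make SUV_peak smaller than
SUV_mean for small lesions.

Background uptake is the mean SUV over the union of 1-cm-diameter axial disk
ROIs placed on normal-appearing bone; the protocol calls for five to ten
ROIs (a warning — not an error — is raised outside that range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .image_model import QuantVolume, voxel_centers
from .segmentation import LesionVOI

__all__ = [
    "UptakeMetrics",
    "BackgroundVOI",
    "SUVRMetrics",
    "suv_max",
    "suv_mean",
    "suv_peak",
    "peak_cube_dims",
    "background_voi",
    "compute_suvr",
    "compute_uptake_metrics",
    "suggest_background_centers",
]


@dataclass
class UptakeMetrics:
    suv_max: float
    suv_peak: float
    suv_mean: float
    peak_cube_anchor: tuple[int, int, int]
    peak_cube_dims: tuple[int, int, int]
    peak_cube_volume_cm3: float


@dataclass
class BackgroundVOI:
    roi_centers_mm: list[tuple[float, float, float]]
    roi_diameter_mm: float
    voxel_indices: np.ndarray  # (n, 3) union set, duplicates removed
    suv_mean_bg: float


@dataclass
class SUVRMetrics:
    suvr_max: float
    suvr_peak: float
    suvr_mean: float


def _voi_values(suv_volume: QuantVolume, voi: LesionVOI) -> np.ndarray:
    if voi.indices.shape[0] == 0:
        raise ValueError("VOI is empty")
    if tuple(voi.grid_shape) != tuple(suv_volume.shape):
        raise ValueError("VOI grid does not match the volume grid")
    return suv_volume.values[tuple(voi.indices.T)]


def suv_max(suv_volume: QuantVolume, voi: LesionVOI) -> float:
    """SUV of the most active voxel within the VOI."""
    return float(_voi_values(suv_volume, voi).max())


def suv_mean(suv_volume: QuantVolume, voi: LesionVOI) -> float:
    """Arithmetic mean SUV over the VOI voxels."""
    return float(_voi_values(suv_volume, voi).mean())


def peak_cube_dims(spacing: tuple[float, float, float], edge_mm: float = 10.0) -> tuple[int, int, int]:
    """Per-axis cube edge in voxels: nearest integer to edge_mm / spacing, min 1."""
    return tuple(max(1, int(np.floor(edge_mm / s + 0.5))) for s in spacing)


def suv_peak(
    suv_volume: QuantVolume, voi: LesionVOI, edge_mm: float = 10.0
) -> tuple[float, tuple[int, int, int], tuple[int, int, int]]:
    """Maximal mean over ~1-cm^3 cubes centered on VOI voxels.

    Returns ``(peak_value, cube_anchor, cube_dims)`` where ``cube_anchor`` is
    the lower corner of the (border-clipped) best cube. Clipped cubes use only
    in-bounds voxels; the cube may include voxels outside the VOI.
    """
    _voi_values(suv_volume, voi)  # validates VOI
    shape = np.array(suv_volume.shape)
    dims = np.array(peak_cube_dims(suv_volume.spacing, edge_mm))

    # summed-area table with a zero border for O(1) box sums
    p = np.zeros(shape + 1)
    p[1:, 1:, 1:] = suv_volume.values.cumsum(0).cumsum(1).cumsum(2)

    centers = voi.indices
    raw_lo = centers - (dims - 1) // 2
    lo = np.clip(raw_lo, 0, shape)
    hi = np.clip(raw_lo + dims, 0, shape)
    l0, l1, l2 = lo.T
    h0, h1, h2 = hi.T
    sums = (
        p[h0, h1, h2] - p[l0, h1, h2] - p[h0, l1, h2] - p[h0, h1, l2]
        + p[l0, l1, h2] + p[l0, h1, l2] + p[h0, l1, l2] - p[l0, l1, l2]
    )
    counts = np.prod(hi - lo, axis=1)
    means = sums / counts
    best = int(np.argmax(means))  # first occurrence -> deterministic (argwhere order)
    anchor = tuple(int(v) for v in lo[best])
    return float(means[best]), anchor, tuple(int(d) for d in dims)


def compute_uptake_metrics(suv_volume: QuantVolume, voi: LesionVOI) -> UptakeMetrics:
    peak, anchor, dims = suv_peak(suv_volume, voi)
    cube_cm3 = float(np.prod(np.array(dims) * np.array(suv_volume.spacing))) / 1000.0
    return UptakeMetrics(
        suv_max=suv_max(suv_volume, voi),
        suv_peak=peak,
        suv_mean=suv_mean(suv_volume, voi),
        peak_cube_anchor=anchor,
        peak_cube_dims=dims,
        peak_cube_volume_cm3=cube_cm3,
    )


def background_voi(
    suv_volume: QuantVolume,
    roi_centers_mm,
    diameter_mm: float = 10.0,
) -> BackgroundVOI:
    """Union of circular axial disk ROIs on normal-appearing bone.

    Each ROI is the set of voxels of one axial slice (the slice whose center
    is nearest the ROI center's z) whose in-plane voxel-center point lies
    within the disk. Overlapping voxels are counted once.
    """
    if diameter_mm <= 0:
        raise ValueError("ROI diameter must be positive")
    centers = [tuple(float(v) for v in c) for c in roi_centers_mm]
    if not centers:
        raise DegenerateInputError("no background ROI centers given")
    if not 5 <= len(centers) <= 10:
        warnings.warn(
            f"{len(centers)} background ROIs; protocol calls for 5-10", stacklevel=2
        )
    sx, sy, sz = suv_volume.spacing
    nx, ny, nz = suv_volume.shape
    xs = voxel_centers(suv_volume.shape, suv_volume.spacing, 0)
    ys = voxel_centers(suv_volume.shape, suv_volume.spacing, 1)
    r2 = (diameter_mm / 2.0) ** 2

    rows: list[np.ndarray] = []
    for cx, cy, cz in centers:
        if not (0 <= cx <= nx * sx and 0 <= cy <= ny * sy and 0 <= cz <= nz * sz):
            raise ValueError(f"ROI center ({cx}, {cy}, {cz}) mm outside the field of view")
        k = int(np.clip(np.floor(cz / sz - 0.5 + 0.5), 0, nz - 1))  # nearest slice center
        inside = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= r2
        ij = np.argwhere(inside)
        if ij.size:
            rows.append(np.column_stack([ij, np.full(len(ij), k, dtype=np.intp)]))
    if not rows:
        raise DegenerateInputError("background ROI union is empty (disks smaller than a voxel?)")
    union = np.unique(np.concatenate(rows, axis=0), axis=0)
    mean_bg = float(suv_volume.values[tuple(union.T)].mean())
    return BackgroundVOI(
        roi_centers_mm=centers,
        roi_diameter_mm=float(diameter_mm),
        voxel_indices=union,
        suv_mean_bg=mean_bg,
    )


def compute_suvr(metrics: UptakeMetrics, bg: BackgroundVOI) -> SUVRMetrics:
    """SUVRs: lesion SUVs divided by the lesion's own background mean SUV."""
    if bg.suv_mean_bg <= 0:
        raise ValueError("background mean SUV must be positive")
    b = bg.suv_mean_bg
    return SUVRMetrics(metrics.suv_max / b, metrics.suv_peak / b, metrics.suv_mean / b)


def suggest_background_centers(
    lesion_center_mm,
    lesion_radius_mm: float,
    fov_mm,
    n_rois: int = 7,
    gap_mm: float = 12.0,
    roi_diameter_mm: float = 10.0,
) -> list[tuple[float, float, float]]:
    """Evenly spaced axial-plane ROI centers on a ring outside a lesion.

    Simulation convenience only — background ROI placement was a manual step
    in the clinical protocol and remains a user input in real analyses.
    """
    cx, cy, cz = (float(v) for v in lesion_center_mm)
    dist = lesion_radius_mm + gap_mm
    pad = roi_diameter_mm / 2.0 + 1.0
    out = []
    for ang in np.linspace(0, 2 * np.pi, n_rois, endpoint=False):
        x = np.clip(cx + dist * np.cos(ang), pad, fov_mm[0] - pad)
        y = np.clip(cy + dist * np.sin(ang), pad, fov_mm[1] - pad)
        out.append((float(x), float(y), cz))
    return out
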