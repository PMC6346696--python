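"""Units, scanner calibration, and the SUV transform over volumetric data.

Conventions
-----------
* Volumes are 3-D scalar arrays tagged with a unit (``cps``, ``Bq_per_ml``,
  or ``SUV``) and per-axis voxel spacing in mm.
* Count-rate volumes store cps *per voxel*; conversion to Bq/ml therefore
  divides by the voxel volume in ml.
* The physical center of voxel ``(i, j, k)`` is ``(i + 0.5, j + 0.5, k + 0.5)
  * spacing`` — a cell-centered grid whose origin is the volume corner.
* Decay correction expresses the injected activity at scan start (decayed
  from injection time to scan time), the standard SUV convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import TYPE_CHECKING

import numpy as np

from .errors import DegenerateInputError, UnitError

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import LesionVOI

__all__ = [
    "UNITS",
    "HALF_LIFE_S",
    "QuantVolume",
    "AcquisitionRecord",
    "CalibrationFactor",
    "decay_correct",
    "compute_calibration_factor",
    "counts_to_concentration",
    "to_suv",
    "voxel_centers",
]

UNITS = ("cps", "Bq_per_ml", "SUV")

#: Isotope half-lives in seconds.
HALF_LIFE_S = {
    "Tc99m": 6.0067 * 3600.0,
    "F18": 109.77 * 60.0,
}


@dataclass
class QuantVolume:
    """A 3-D scalar field with voxel spacing metadata and a unit tag.

    Parameters
    ----------
    values : numpy.ndarray
        3-D array of voxel values, unit given by ``unit``.
    spacing : tuple of float
        Per-axis voxel edge length in mm; all components must be positive.
    unit : str
        One of ``cps``, ``Bq_per_ml``, ``SUV``.
    modality : str
        Free label such as ``"SPECT"`` or ``"PET"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    unit: str
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        # 1 ml = 1 cm^3 = 1000 mm^3
        return self.voxel_volume_mm3 / 1000.0

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        """Physical extent of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "QuantVolume":
        """Copy of this volume with new voxel data (and optionally a new unit tag)."""
        return QuantVolume(values, self.spacing, unit or self.unit, self.modality)


def voxel_centers(shape: tuple[int, ...], spacing: tuple[float, ...], axis: int) -> np.ndarray:
    """Physical coordinates (mm) of voxel centers along one axis."""
    return (np.arange(shape[axis]) + 0.5) * spacing[axis]


@dataclass
class AcquisitionRecord:
    """Per-scan acquisition bookkeeping: the non-voxel symbols of the SUV formula.

    Activities are in Bq, weight in g, half-life in seconds.
    """

    injected_activity_bq: float
    t_injection: datetime
    t_scan: datetime
    patient_weight_g: float
    half_life_s: float
    isotope: str = ""

    def __post_init__(self) -> None:
        if self.injected_activity_bq <= 0:
            raise ValueError("injected activity must be positive")
        if self.patient_weight_g <= 0:
            raise ValueError("patient weight must be positive")
        if self.half_life_s <= 0:
            raise ValueError("half-life must be positive")
        if self.t_scan < self.t_injection:
            raise ValueError("scan time precedes injection time")

    @property
    def uptake_time_s(self) -> float:
        return (self.t_scan - self.t_injection).total_seconds()

    def decayed_activity_bq(self) -> float:
        """Injected activity decay-corrected to scan start."""
        return decay_correct(self.injected_activity_bq, self.uptake_time_s, self.half_life_s)


@dataclass
class CalibrationFactor:
    """Scanner conversion factor in kBq per cps, from a uniform-phantom session."""

    value_kbq_per_cps: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.value_kbq_per_cps <= 0:
            raise ValueError("calibration factor must be positive")


def decay_correct(activity_bq: float, elapsed_s: float, half_life_s: float) -> float:
    """Radioactive decay of ``activity_bq`` over ``elapsed_s`` seconds.

    Returns ``activity * 2**(-elapsed / half_life)``.
    """
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    if elapsed_s < 0:
        raise ValueError("elapsed time must be non-negative")
    if activity_bq < 0:
        raise ValueError("activity must be non-negative")
    return activity_bq * math.pow(2.0, -elapsed_s / half_life_s)


def compute_calibration_factor(
    counts_volume: QuantVolume,
    true_activity_kbq: float,
    voi: "LesionVOI",
    source: str = "",
) -> CalibrationFactor:
    """Conversion factor = true activity in a homogeneous VOI / reconstructed count rate.

    Homogeneity of the VOI is the caller's responsibility.
    """
    if counts_volume.unit != "cps":
        raise UnitError(f"calibration needs a cps volume, got {counts_volume.unit}")
    if true_activity_kbq <= 0:
        raise ValueError("true activity must be positive")
    idx = voi.indices
    if idx.shape[0] == 0:
        raise ValueError("VOI is empty")
    if np.any(idx < 0) or np.any(idx >= np.array(counts_volume.shape)):
        raise ValueError("VOI extends outside the counts volume")
    total_cps = float(counts_volume.values[tuple(idx.T)].sum())
    if total_cps <= 0:
        raise DegenerateInputError("total reconstructed count rate in VOI is not positive")
    return CalibrationFactor(true_activity_kbq / total_cps, source=source)


def counts_to_concentration(
    counts_volume: QuantVolume, factor: CalibrationFactor
) -> QuantVolume:
    """Convert a per-voxel count-rate volume to activity concentration (Bq/ml)."""
    if counts_volume.unit != "cps":
        raise UnitError(f"expected cps volume, got {counts_volume.unit}")
    bq_per_voxel = counts_volume.values * factor.value_kbq_per_cps * 1000.0
    return counts_volume.with_values(bq_per_voxel / counts_volume.voxel_volume_ml, unit="Bq_per_ml")


def to_suv(conc_volume: QuantVolume, acq: AcquisitionRecord) -> QuantVolume:
    """SUV = concentration (Bq/ml) x patient weight (g) / decay-corrected injected activity (Bq).

    Dimensionless under the 1 ml/g convention.
    """
    if conc_volume.unit != "Bq_per_ml":
        raise UnitError(f"expected Bq_per_ml volume, got {conc_volume.unit}")
    activity = acq.decayed_activity_bq()
    if activity <= 0:
        raise ValueError("decay-corrected injected activity must be positive")
    return conc_volume.with_values(
        conc_volume.values * acq.patient_weight_g / activity, unit="SUV"
    )
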