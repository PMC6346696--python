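"""Paired digital-phantom generation with known ground truth.

Spherical focal lesions over uniform bone-like background are rasterized by
voxel-center membership onto two grids sharing one physical field of view:
a SPECT-like grid (default 4.8 mm isotropic) and a PET-like grid (default
3.65 x 3.65 x 3.27 mm; a 5.47 mm in-plane alternative is supported). PET
voxel values are the SPECT values times a programmable uptake ratio. The
measurement system is modeled as a single effective Gaussian blur per
modality (reconstruction and postfilter combined; defaults SPECT 12 mm,
PET 8 mm FWHM — conventions, since total system resolution is scanner
software dependent) plus optional signal-scaled Gaussian noise. A counts
branch inverts the calibration path so calibration round trips can be
exercised end to end.

All randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy import ndimage

from .errors import GenerationError
from .image_model import (
    HALF_LIFE_S,
    AcquisitionRecord,
    CalibrationFactor,
    QuantVolume,
    voxel_centers,
)
from .segmentation import SITES

__all__ = [
    "FWHM_TO_SIGMA",
    "DEFAULT_SITE_BACKGROUND_SUV",
    "LesionDef",
    "PhantomSpec",
    "GroundTruth",
    "CohortCase",
    "rasterize_phantom",
    "apply_system_model",
    "to_counts_branch",
    "make_paired_cohort",
    "default_acquisition",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548

# Site-wise normal-bone background levels (SUV-equivalent) used as simulator
# defaults for the SPECT channel; PET backgrounds follow via the uptake ratio.
DEFAULT_SITE_BACKGROUND_SUV = {
    "skull": 2.0,
    "spine": 6.1,
    "rib_cage": 2.5,
    "pelvis": 4.7,
    "limbs": 3.2,
}

DEFAULT_SPECT_SPACING = (4.8, 4.8, 4.8)
DEFAULT_PET_SPACING = (3.65, 3.65, 3.27)
ALT_PET_SPACING = (5.47, 5.47, 3.27)


@dataclass
class LesionDef:
    """One spherical lesion: center/radius in mm, SPECT-channel value, labels."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    spect_value: float
    site: str = "spine"
    lesion_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.spect_value <= 0:
            raise ValueError("lesion value must be positive")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")

    @property
    def volume_cm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm**3 / 1000.0


@dataclass
class PhantomSpec:
    """Ground-truth description of one paired phantom."""

    shape_spect: tuple[int, int, int]
    shape_pet: tuple[int, int, int]
    spacing_spect: tuple[float, float, float] = DEFAULT_SPECT_SPACING
    spacing_pet: tuple[float, float, float] = DEFAULT_PET_SPACING
    lesions: list[LesionDef] = field(default_factory=list)
    background: float = 5.0
    uptake_ratio: float = 1.2
    psf_fwhm_mm: dict = field(default_factory=lambda: {"SPECT": 12.0, "PET": 8.0})
    noise_model: str = "none"  # none | gaussian_scaled
    noise_scale: float = 0.0
    calibration_factor_kbq_per_cps: float = 0.107
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background level must be positive")
        if self.uptake_ratio <= 0:
            raise ValueError("uptake ratio must be positive")
        if any(f < 0 for f in self.psf_fwhm_mm.values()):
            raise ValueError("PSF FWHM must be non-negative")
        if self.noise_model not in ("none", "gaussian_scaled"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        fov_s = np.array(self.shape_spect) * np.array(self.spacing_spect)
        fov_p = np.array(self.shape_pet) * np.array(self.spacing_pet)
        tol = max(max(self.spacing_spect), max(self.spacing_pet))
        if np.any(np.abs(fov_s - fov_p) > tol):
            raise ValueError(
                f"grids must share one physical field of view; got {fov_s} vs {fov_p} mm"
            )

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape_spect, self.spacing_spect))


@dataclass
class GroundTruth:
    """What the generator programmed, for downstream recovery checks."""

    lesions: list[dict]
    background: dict
    uptake_ratio: float
    psf_fwhm_mm: dict
    calibration_factor_kbq_per_cps: float
    seed: int


def _sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    """Voxel-center membership rasterization of a sphere (no anti-aliasing)."""
    xs = voxel_centers(shape, spacing, 0)
    ys = voxel_centers(shape, spacing, 1)
    zs = voxel_centers(shape, spacing, 2)
    d2 = (
        (xs[:, None, None] - center_mm[0]) ** 2
        + (ys[None, :, None] - center_mm[1]) ** 2
        + (zs[None, None, :] - center_mm[2]) ** 2
    )
    return d2 <= radius_mm**2


def rasterize_phantom(spec: PhantomSpec) -> tuple[dict[str, QuantVolume], GroundTruth]:
    """Analytic spheres onto both grids; lesion value overrides background.

    Returns noiseless, blur-free "true" volumes (unit Bq_per_ml; values are on
    whatever scale the spec's lesion/background values use) plus the ground
    truth. PET values are SPECT values times the uptake ratio.
    """
    fov = np.array(spec.fov_mm)
    truth_lesions = []
    grids = {
        "SPECT": (spec.shape_spect, spec.spacing_spect, 1.0),
        "PET": (spec.shape_pet, spec.spacing_pet, spec.uptake_ratio),
    }
    arrays = {
        mod: np.full(shape, spec.background * ratio)
        for mod, (shape, spacing, ratio) in grids.items()
    }
    for li, lesion in enumerate(spec.lesions):
        c = np.array(lesion.center_mm)
        if np.any(c - lesion.radius_mm < 0) or np.any(c + lesion.radius_mm > fov):
            raise ValueError(f"lesion {li} extends outside the field of view")
        counts = {}
        for mod, (shape, spacing, ratio) in grids.items():
            mask = _sphere_mask(shape, spacing, lesion.center_mm, lesion.radius_mm)
            arrays[mod][mask] = lesion.spect_value * ratio
            counts[mod] = int(mask.sum())
        truth_lesions.append(
            {
                "index": li,
                "center_mm": list(lesion.center_mm),
                "radius_mm": lesion.radius_mm,
                "analytic_volume_cm3": lesion.volume_cm3,
                "spect_value": lesion.spect_value,
                "pet_value": lesion.spect_value * spec.uptake_ratio,
                "voxel_count_spect": counts["SPECT"],
                "voxel_count_pet": counts["PET"],
                "site": lesion.site,
                "lesion_class": lesion.lesion_class,
            }
        )
    volumes = {
        mod: QuantVolume(arrays[mod], grids[mod][1], "Bq_per_ml", modality=mod)
        for mod in grids
    }
    truth = GroundTruth(
        lesions=truth_lesions,
        background={"SPECT": spec.background, "PET": spec.background * spec.uptake_ratio},
        uptake_ratio=spec.uptake_ratio,
        psf_fwhm_mm=dict(spec.psf_fwhm_mm),
        calibration_factor_kbq_per_cps=spec.calibration_factor_kbq_per_cps,
        seed=spec.seed,
    )
    return volumes, truth


def apply_system_model(
    true_volume: QuantVolume,
    fwhm_mm: float,
    noise_model: str = "none",
    noise_scale: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> QuantVolume:
    """Effective system response: separable Gaussian blur plus optional noise.

    Blur uses sigma = FWHM / 2.3548 per axis (converted to voxels via the
    spacing) with zero padding at borders. ``gaussian_scaled`` noise adds
    independent Gaussian noise with SD = noise_scale * sqrt(value), clipped
    at zero. Deterministic under a fixed seed.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    values = true_volume.values
    if fwhm_mm > 0:
        sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in true_volume.spacing]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="constant", cval=0.0)
    if noise_model == "gaussian_scaled" and noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(np.clip(values, 0, None))
        values = np.clip(values + rng.normal(0.0, 1.0, values.shape) * sd, 0.0, None)
    elif noise_model not in ("none", "gaussian_scaled"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    return true_volume.with_values(values)


def to_counts_branch(conc_volume: QuantVolume, factor: CalibrationFactor) -> QuantVolume:
    """Exact inverse of counts_to_concentration: Bq/ml -> per-voxel cps."""
    if conc_volume.unit != "Bq_per_ml":
        raise ValueError(f"expected Bq_per_ml volume, got {conc_volume.unit}")
    cps = conc_volume.values * conc_volume.voxel_volume_ml / (factor.value_kbq_per_cps * 1000.0)
    return conc_volume.with_values(cps, unit="cps")


def default_acquisition(modality: str, weight_g: float = 70000.0) -> AcquisitionRecord:
    """Typical bone-scan acquisition records for the two modalities."""
    t0 = datetime(2020, 1, 1, 9, 0, 0)
    if modality.upper() == "SPECT":
        return AcquisitionRecord(
            injected_activity_bq=672e6,
            t_injection=t0,
            t_scan=t0 + timedelta(minutes=180),
            patient_weight_g=weight_g,
            half_life_s=HALF_LIFE_S["Tc99m"],
            isotope="Tc99m",
        )
    return AcquisitionRecord(
        injected_activity_bq=209e6,
        t_injection=t0,
        t_scan=t0 + timedelta(minutes=64),
        patient_weight_g=weight_g,
        half_life_s=HALF_LIFE_S["F18"],
        isotope="F18",
    )


@dataclass
class CohortCase:
    """One simulated lesion: a paired phantom patch plus everything the
    analysis pipeline needs (seeds, background ROI centers, acquisitions)."""

    lesion_id: str
    site: str
    lesion_class: str
    spect: QuantVolume  # Bq/ml, measured (blur/noise applied)
    pet: QuantVolume
    acq_spect: AcquisitionRecord
    acq_pet: AcquisitionRecord
    seed_spect: tuple[int, int, int]
    seed_pet: tuple[int, int, int]
    bg_centers_mm: list[tuple[float, float, float]]
    truth: dict


def _center_voxel(center_mm, spacing, shape) -> tuple[int, int, int]:
    idx = tuple(int(np.clip(np.floor(c / s), 0, n - 1)) for c, s, n in zip(center_mm, spacing, shape))
    return idx


def _case_grids(radius_mm: float, margin_mm: float):
    fov = 2.0 * (radius_mm + margin_mm)
    shape_s = tuple(int(math.ceil(fov / s)) for s in DEFAULT_SPECT_SPACING)
    fov_actual = tuple(n * s for n, s in zip(shape_s, DEFAULT_SPECT_SPACING))
    shape_p = tuple(
        int(round(f / s)) for f, s in zip(fov_actual, DEFAULT_PET_SPACING)
    )
    return shape_s, shape_p, fov_actual


def make_paired_cohort(
    n_lesions: int,
    seed: int,
    uptake_ratio: float = 1.2,
    psf_fwhm_mm: dict | None = None,
    noise_model: str = "none",
    noise_scale: float = 0.0,
    radius_range_mm: tuple[float, float] = (5.1, 24.0),
    suv_log_mean: float = math.log(28.0),
    suv_log_sigma: float = 0.25,
    suv_floor: float = 18.0,
    metastatic_fraction: float = 0.55,
    metastatic_suv_factor: float = 1.35,
    site_background_suv: dict | None = None,
    weight_g: float = 70000.0,
    n_bg_rois: int = 7,
) -> list[CohortCase]:
    """Simulate a cohort of paired single-lesion phantom patches.

    Each lesion lives in its own small paired volume (one lesion per patch,
    so packing is trivially feasible). Lesion radii are log-uniform over
    ``radius_range_mm`` (covering roughly 0.5-60 cm^3), SPECT-channel lesion
    SUVs are lognormal with a floor, sites are drawn uniformly with
    site-dependent background, and metastatic lesions get a multiplicative
    SUV shift. Concentration volumes are scaled so the default acquisition
    records map them onto the programmed SUVs exactly.
    """
    if n_lesions < 1:
        raise GenerationError("cohort must contain at least one lesion")
    rng = np.random.default_rng(seed)
    fwhm = dict(psf_fwhm_mm or {"SPECT": 12.0, "PET": 8.0})
    bg_site = dict(site_background_suv or DEFAULT_SITE_BACKGROUND_SUV)
    acq_s = default_acquisition("SPECT", weight_g)
    acq_p = default_acquisition("PET", weight_g)
    # conversion: concentration = SUV * A_decayed / weight, per modality
    k_s = acq_s.decayed_activity_bq() / weight_g
    k_p = acq_p.decayed_activity_bq() / weight_g

    max_fwhm = max(fwhm.values()) if fwhm else 0.0
    gap_mm = 3.0 * max_fwhm * FWHM_TO_SIGMA + 8.0  # keep bg ROIs out of the lesion halo
    margin_mm = gap_mm + 10.0  # room for the ROI ring plus a border pad

    cases: list[CohortCase] = []
    for i in range(n_lesions):
        radius = math.exp(rng.uniform(math.log(radius_range_mm[0]), math.log(radius_range_mm[1])))
        site = str(rng.choice(SITES))
        lesion_class = "metastatic" if rng.random() < metastatic_fraction else "benign"
        suv = max(suv_floor, float(rng.lognormal(suv_log_mean, suv_log_sigma)))
        if lesion_class == "metastatic":
            suv *= metastatic_suv_factor
        bg_suv = bg_site[site]

        shape_s, shape_p, fov = _case_grids(radius, margin_mm)
        center = tuple(f / 2.0 for f in fov)
        spec = PhantomSpec(
            shape_spect=shape_s,
            shape_pet=shape_p,
            lesions=[
                LesionDef(center, radius, suv * k_s, site=site, lesion_class=lesion_class)
            ],
            background=bg_suv * k_s,
            uptake_ratio=uptake_ratio * (k_p / k_s),
            psf_fwhm_mm=fwhm,
            noise_model=noise_model,
            noise_scale=noise_scale,
            seed=seed + i,
        )
        volumes, truth = rasterize_phantom(spec)
        measured = {}
        for mod in ("SPECT", "PET"):
            measured[mod] = apply_system_model(
                volumes[mod],
                fwhm.get(mod, 0.0),
                noise_model=noise_model,
                noise_scale=noise_scale * (k_s if mod == "SPECT" else k_p) ** 0.5,
                rng=rng,
            )
        bg_centers = _ring_centers(center, radius, gap_mm, fov, n_bg_rois)
        cases.append(
            CohortCase(
                lesion_id=f"L{i:04d}",
                site=site,
                lesion_class=lesion_class,
                spect=measured["SPECT"],
                pet=measured["PET"],
                acq_spect=acq_s,
                acq_pet=acq_p,
                seed_spect=_center_voxel(center, DEFAULT_SPECT_SPACING, shape_s),
                seed_pet=_center_voxel(center, DEFAULT_PET_SPACING, shape_p),
                bg_centers_mm=bg_centers,
                truth={
                    "lesion_id": f"L{i:04d}",
                    "radius_mm": radius,
                    "analytic_volume_cm3": 4.0 / 3.0 * math.pi * radius**3 / 1000.0,
                    "suv_spect": suv,
                    "suv_pet": suv * uptake_ratio,
                    "bg_suv_spect": bg_suv,
                    "bg_suv_pet": bg_suv * uptake_ratio,
                    "uptake_ratio": uptake_ratio,
                    "site": site,
                    "lesion_class": lesion_class,
                    "voxel_count_spect": truth.lesions[0]["voxel_count_spect"],
                    "voxel_count_pet": truth.lesions[0]["voxel_count_pet"],
                },
            )
        )
    return cases


def _ring_centers(center_mm, radius_mm, gap_mm, fov_mm, n_rois):
    """Background ROI centers on an axial ring outside the lesion."""
    cx, cy, cz = center_mm
    dist = radius_mm + gap_mm
    pad = 6.0
    out = []
    for ang in np.linspace(0.0, 2.0 * math.pi, n_rois, endpoint=False):
        x = float(np.clip(cx + dist * math.cos(ang), pad, fov_mm[0] - pad))
        y = float(np.clip(cy + dist * math.sin(ang), pad, fov_mm[1] - pad))
        out.append((x, y, cz))
    return out
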