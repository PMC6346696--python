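"""End-to-end per-lesion analysis: segmentation -> metrics -> paired records.

The reference modality (PET by default) is segmented with a fixed SUV
threshold (default > 15); the paired modality is segmented at the threshold
whose VOI volume best matches the reference VOI volume. A ``relative``
threshold policy is available for simulation runs where heavy blur pushes
lesions below a fixed threshold — it stands in for the manual threshold
lowering of the clinical protocol and sets the threshold at a fixed fraction
of the seed-to-background contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import (
    bland_altman_median,
    least_squares_fit,
    mann_whitney_u,
    normality_gate,
    site_background_summary,
    size_stratified_summary,
    wilcoxon_signed_rank,
)
from .errors import SuvkitError
from .image_model import AcquisitionRecord, QuantVolume, to_suv
from .metrics import (
    BackgroundVOI,
    SUVRMetrics,
    UptakeMetrics,
    background_voi,
    compute_suvr,
    compute_uptake_metrics,
)
from .phantom import CohortCase
from .segmentation import LesionVOI, match_volume_threshold, segment_threshold

__all__ = [
    "AnalysisOptions",
    "ModalityResult",
    "PairedLesionRecord",
    "analyze_case",
    "analyze_cohort",
    "lesion_frame",
    "paired_frame",
    "agreement_report",
    "SUV_MEASURES",
    "SUVR_MEASURES",
]

SUV_MEASURES = ("suv_max", "suv_peak", "suv_mean")
SUVR_MEASURES = ("suvr_max", "suvr_peak", "suvr_mean")


@dataclass
class AnalysisOptions:
    threshold: float = 15.0
    threshold_policy: str = "fixed"  # fixed | relative
    relative_fraction: float = 0.5
    max_rel_mismatch: float = 0.20
    bg_diameter_mm: float = 10.0
    reference: str = "PET"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.threshold_policy not in ("fixed", "relative"):
            raise ValueError(f"unknown threshold policy {self.threshold_policy!r}")
        if not 0 < self.relative_fraction < 1:
            raise ValueError("relative fraction must be in (0, 1)")


@dataclass
class ModalityResult:
    modality: str
    voi: LesionVOI
    metrics: UptakeMetrics
    background: BackgroundVOI
    suvr: SUVRMetrics
    volume_cm3: float
    threshold: float
    achieved_mismatch: float | None


@dataclass
class PairedLesionRecord:
    lesion_id: str
    site: str
    lesion_class: str
    reference: str
    spect: ModalityResult
    pet: ModalityResult
    truth: dict = field(default_factory=dict)


def _as_suv(volume: QuantVolume, acq: AcquisitionRecord | None) -> QuantVolume:
    if volume.unit == "SUV":
        return volume
    if volume.unit == "Bq_per_ml":
        if acq is None:
            raise ValueError("concentration volume needs an acquisition record")
        return to_suv(volume, acq)
    raise ValueError(f"cannot convert {volume.unit} volume to SUV without calibration")


def _effective_threshold(
    suv_volume: QuantVolume, seed, options: AnalysisOptions, override: float | None
) -> float:
    if override is not None and override > 0:
        return float(override)
    if options.threshold_policy == "fixed":
        return options.threshold
    bg_est = float(np.median(suv_volume.values))
    seed_val = float(suv_volume.values[tuple(int(v) for v in seed)])
    return bg_est + options.relative_fraction * (seed_val - bg_est)


def _modality_result(
    suv_vol: QuantVolume, voi: LesionVOI, bg_centers, options: AnalysisOptions, modality: str
) -> ModalityResult:
    metrics = compute_uptake_metrics(suv_vol, voi)
    bg = background_voi(suv_vol, bg_centers, options.bg_diameter_mm)
    return ModalityResult(
        modality=modality,
        voi=voi,
        metrics=metrics,
        background=bg,
        suvr=compute_suvr(metrics, bg),
        volume_cm3=voi.volume_cm3,
        threshold=voi.threshold,
        achieved_mismatch=voi.achieved_mismatch,
    )


def analyze_case(
    case: CohortCase,
    options: AnalysisOptions | None = None,
    threshold_override: float | None = None,
    vois: dict[str, LesionVOI] | None = None,
) -> PairedLesionRecord:
    """Analyze one paired lesion case end to end.

    If ``vois`` is given ({"SPECT": ..., "PET": ...}), segmentation is skipped
    and metrics are computed on the provided VOIs (used e.g. to demonstrate
    calibration invariance of SUVRs with the segmentation held fixed).
    """
    options = options or AnalysisOptions()
    suv = {
        "SPECT": _as_suv(case.spect, case.acq_spect),
        "PET": _as_suv(case.pet, case.acq_pet),
    }
    seeds = {"SPECT": case.seed_spect, "PET": case.seed_pet}
    ref = options.reference.upper()
    other = "SPECT" if ref == "PET" else "PET"
    if vois is None:
        t_ref = _effective_threshold(suv[ref], seeds[ref], options, threshold_override)
        ref_voi = segment_threshold(
            suv[ref], seeds[ref], t_ref, site=case.site, lesion_class=case.lesion_class
        )
        other_voi = match_volume_threshold(
            suv[other],
            seeds[other],
            ref_voi.volume_cm3,
            max_rel_mismatch=options.max_rel_mismatch,
            site=case.site,
            lesion_class=case.lesion_class,
        )
        vois = {ref: ref_voi, other: other_voi}
    results = {
        mod: _modality_result(suv[mod], vois[mod], case.bg_centers_mm, options, mod)
        for mod in ("SPECT", "PET")
    }
    return PairedLesionRecord(
        lesion_id=case.lesion_id,
        site=case.site,
        lesion_class=case.lesion_class,
        reference=ref,
        spect=results["SPECT"],
        pet=results["PET"],
        truth=dict(case.truth),
    )


def analyze_cohort(
    cases,
    options: AnalysisOptions | None = None,
    threshold_overrides: dict[str, float] | None = None,
):
    """Analyze a list of cases; per-lesion failures are collected, not fatal.

    Returns ``(records, failures)`` where ``failures`` maps lesion_id to the
    error message of any lesion that could not be segmented or matched.
    """
    options = options or AnalysisOptions()
    overrides = threshold_overrides or {}
    records: list[PairedLesionRecord] = []
    failures: dict[str, str] = {}
    for case in cases:
        try:
            records.append(
                analyze_case(case, options, threshold_override=overrides.get(case.lesion_id))
            )
        except SuvkitError as exc:
            failures[case.lesion_id] = f"{type(exc).__name__}: {exc}"
    return records, failures


def lesion_frame(records) -> pd.DataFrame:
    """Long per-lesion metrics table: one row per lesion and modality."""
    rows = []
    for rec in records:
        for res in (rec.spect, rec.pet):
            rows.append(
                {
                    "lesion_id": rec.lesion_id,
                    "modality": res.modality,
                    "volume_cm3": res.volume_cm3,
                    "threshold": res.threshold,
                    "suv_max": res.metrics.suv_max,
                    "suv_peak": res.metrics.suv_peak,
                    "suv_mean": res.metrics.suv_mean,
                    "suv_mean_bg": res.background.suv_mean_bg,
                    "suvr_max": res.suvr.suvr_max,
                    "suvr_peak": res.suvr.suvr_peak,
                    "suvr_mean": res.suvr.suvr_mean,
                    "site": rec.site,
                    "class": rec.lesion_class,
                }
            )
    return pd.DataFrame(rows)


def paired_frame(records) -> pd.DataFrame:
    """Wide per-lesion table with ``<measure>_spect`` / ``<measure>_pet`` columns."""
    rows = []
    for rec in records:
        row = {
            "lesion_id": rec.lesion_id,
            "site": rec.site,
            "class": rec.lesion_class,
            # stratification volume: the reference-modality VOI volume
            "volume_cm3": (rec.pet if rec.reference == "PET" else rec.spect).volume_cm3,
            "volume_mismatch": (
                rec.spect if rec.reference == "PET" else rec.pet
            ).achieved_mismatch,
        }
        for res, tag in ((rec.spect, "spect"), (rec.pet, "pet")):
            row[f"volume_cm3_{tag}"] = res.volume_cm3
            row[f"suv_max_{tag}"] = res.metrics.suv_max
            row[f"suv_peak_{tag}"] = res.metrics.suv_peak
            row[f"suv_mean_{tag}"] = res.metrics.suv_mean
            row[f"suv_mean_bg_{tag}"] = res.background.suv_mean_bg
            row[f"suvr_max_{tag}"] = res.suvr.suvr_max
            row[f"suvr_peak_{tag}"] = res.suvr.suvr_peak
            row[f"suvr_mean_{tag}"] = res.suvr.suvr_mean
        rows.append(row)
    return pd.DataFrame(rows)


def agreement_report(paired: pd.DataFrame, n_strata: int = 4) -> dict:
    """Full agreement analysis over a wide paired-lesion table.

    Per SUV/SUVR measure: least-squares regression (SPECT on x, PET on y),
    nonparametric Bland-Altman, Wilcoxon signed-rank on the paired
    differences, and a Shapiro-Wilk gate on the differences. Plus
    metastatic-vs-benign Mann-Whitney tests per modality and measure,
    volume-stratified difference summaries, and per-site background medians.
    """
    report: dict = {"n_lesions": int(len(paired)), "measures": {}}
    for meas in SUV_MEASURES + SUVR_MEASURES:
        spect = paired[f"{meas}_spect"].to_numpy(dtype=float)
        pet = paired[f"{meas}_pet"].to_numpy(dtype=float)
        reg = least_squares_fit(spect, pet)
        ba = bland_altman_median(spect, pet)
        w, p_w, method = wilcoxon_signed_rank(pet - spect)
        try:
            is_normal, p_sw = normality_gate(ba.differences)
        except ValueError:
            is_normal, p_sw = False, float("nan")
        entry = {
            "regression": {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "n": reg.n,
            },
            "bland_altman": {
                "median_diff_pct": ba.median_diff_pct,
                "loa_low_pct": ba.loa_low_pct,
                "loa_high_pct": ba.loa_high_pct,
                "normalization": ba.normalization,
            },
            "wilcoxon": {"w": w, "p": p_w, "method": method},
            "shapiro": {"is_normal": is_normal, "p": p_sw},
        }
        if {"metastatic", "benign"} <= set(paired["class"]):
            mwu = {}
            for tag in ("spect", "pet"):
                met = paired.loc[paired["class"] == "metastatic", f"{meas}_{tag}"]
                ben = paired.loc[paired["class"] == "benign", f"{meas}_{tag}"]
                u, p_u, m_u = mann_whitney_u(met, ben, alternative="greater")
                mwu[tag] = {"u": u, "p_one_sided": p_u, "method": m_u}
            entry["mann_whitney_metastatic_gt_benign"] = mwu
        report["measures"][meas] = entry
    if len(paired) >= n_strata:
        report["size_strata"] = size_stratified_summary(paired, n_strata=n_strata).to_dict(
            orient="records"
        )
    report["site_background"] = site_background_summary(paired).to_dict(orient="records")
    return report
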