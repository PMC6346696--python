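"""File formats: NIfTI volumes, CSV tables, acquisition records, bundles.

Volumes are NIfTI-1 with voxel spacing taken from the header zooms. Lesion
seeds and metadata live in a CSV with columns
``lesion_id, modality, i, j, k, site, class, threshold_override``; background
ROI centers in a CSV with ``lesion_id, x_mm, y_mm, z_mm``. Acquisition
records are JSON or YAML with ISO-8601 timestamps and activities in MBq
(converted to Bq internally).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .image_model import HALF_LIFE_S, AcquisitionRecord, QuantVolume
from .segmentation import LesionVOI

__all__ = [
    "load_volume",
    "save_volume",
    "save_voi_mask",
    "load_acquisition",
    "save_acquisition",
    "read_seed_table",
    "write_seed_table",
    "read_bg_rois",
    "write_bg_rois",
    "write_cohort_bundle",
    "read_cohort_bundle",
    "sha256_file",
]

SEED_COLUMNS = ["lesion_id", "modality", "i", "j", "k", "site", "class", "threshold_override"]
BG_COLUMNS = ["lesion_id", "x_mm", "y_mm", "z_mm"]


def load_volume(path, unit: str, modality: str = "") -> QuantVolume:
    """Read a NIfTI-1 volume; spacing comes from the header zooms (pixdim)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return QuantVolume(data, spacing, unit, modality=modality)


def save_volume(volume: QuantVolume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))


def save_voi_mask(voi: LesionVOI, path, label: int = 1) -> None:
    """Export a VOI as a NIfTI label mask on its grid."""
    mask = np.zeros(voi.grid_shape, dtype=np.uint8)
    mask[tuple(voi.indices.T)] = label
    affine = np.diag(list(voi.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask, affine), str(path))


def _acq_to_dict(acq: AcquisitionRecord) -> dict:
    return {
        "injected_activity_MBq": acq.injected_activity_bq / 1e6,
        "t_injection": acq.t_injection.isoformat(),
        "t_scan": acq.t_scan.isoformat(),
        "patient_weight_g": acq.patient_weight_g,
        "half_life_s": acq.half_life_s,
        "isotope": acq.isotope,
    }


def _acq_from_dict(d: dict) -> AcquisitionRecord:
    if "half_life_s" in d and d["half_life_s"]:
        half_life = float(d["half_life_s"])
    else:
        isotope = d.get("isotope", "")
        if isotope not in HALF_LIFE_S:
            raise ValueError(f"need half_life_s or a known isotope, got {isotope!r}")
        half_life = HALF_LIFE_S[isotope]
    return AcquisitionRecord(
        injected_activity_bq=float(d["injected_activity_MBq"]) * 1e6,
        t_injection=datetime.fromisoformat(str(d["t_injection"])),
        t_scan=datetime.fromisoformat(str(d["t_scan"])),
        patient_weight_g=float(d["patient_weight_g"]),
        half_life_s=half_life,
        isotope=d.get("isotope", ""),
    )


def load_acquisition(path) -> AcquisitionRecord:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _acq_from_dict(d)


def save_acquisition(acq: AcquisitionRecord, path) -> None:
    path = Path(path)
    d = _acq_to_dict(acq)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def read_seed_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SEED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"seed table missing columns: {sorted(missing)}")
    bad = df[df[["i", "j", "k"]].isna().any(axis=1)]
    if not bad.empty:
        raise ValueError(f"seed table has rows without voxel indices: {bad.index.tolist()}")
    return df


def write_seed_table(rows, path) -> None:
    pd.DataFrame(rows, columns=SEED_COLUMNS).to_csv(path, index=False)


def read_bg_rois(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"background ROI table missing columns: {sorted(missing)}")
    return df


def write_bg_rois(rows, path) -> None:
    pd.DataFrame(rows, columns=BG_COLUMNS).to_csv(path, index=False)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_cohort_bundle(cases, out_dir) -> dict:
    """Write a simulated cohort to disk: paired NIfTI volumes per case, a
    lesion-seed CSV, a background-ROI CSV, acquisition records, ground-truth
    JSON, and a manifest with sha256 hashes of every file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_rows, bg_rows, truth = [], [], []
    files = []
    for case in cases:
        for mod, vol, seed in (
            ("SPECT", case.spect, case.seed_spect),
            ("PET", case.pet, case.seed_pet),
        ):
            fname = f"{case.lesion_id}_{mod.lower()}.nii"
            save_volume(vol, out / fname)
            files.append(fname)
            seed_rows.append(
                {
                    "lesion_id": case.lesion_id,
                    "modality": mod,
                    "i": seed[0], "j": seed[1], "k": seed[2],
                    "site": case.site,
                    "class": case.lesion_class,
                    "threshold_override": "",
                }
            )
        for x, y, z in case.bg_centers_mm:
            bg_rows.append({"lesion_id": case.lesion_id, "x_mm": x, "y_mm": y, "z_mm": z})
        truth.append(case.truth)
    write_seed_table(seed_rows, out / "seeds.csv")
    write_bg_rois(bg_rows, out / "bg_rois.csv")
    save_acquisition(cases[0].acq_spect, out / "acq_spect.json")
    save_acquisition(cases[0].acq_pet, out / "acq_pet.json")
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    files += ["seeds.csv", "bg_rois.csv", "acq_spect.json", "acq_pet.json", "truth.json"]
    manifest = {
        "n_cases": len(cases),
        "files": {f: sha256_file(out / f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort_bundle(bundle_dir):
    """Load a cohort bundle written by :func:`write_cohort_bundle`."""
    from .phantom import CohortCase  # local import to avoid a cycle

    bundle = Path(bundle_dir)
    seeds = read_seed_table(bundle / "seeds.csv")
    bg = read_bg_rois(bundle / "bg_rois.csv")
    acq_spect = load_acquisition(bundle / "acq_spect.json")
    acq_pet = load_acquisition(bundle / "acq_pet.json")
    truth = {t["lesion_id"]: t for t in json.loads((bundle / "truth.json").read_text())}
    cases = []
    for lesion_id, group in seeds.groupby("lesion_id", sort=True):
        by_mod = {row["modality"]: row for _, row in group.iterrows()}
        if set(by_mod) != {"SPECT", "PET"}:
            raise ValueError(f"lesion {lesion_id} needs one SPECT and one PET seed row")
        vols, seed_idx = {}, {}
        for mod, row in by_mod.items():
            vols[mod] = load_volume(
                bundle / f"{lesion_id}_{mod.lower()}.nii", unit="Bq_per_ml", modality=mod
            )
            seed_idx[mod] = (int(row["i"]), int(row["j"]), int(row["k"]))
        centers = [
            (r["x_mm"], r["y_mm"], r["z_mm"])
            for _, r in bg[bg["lesion_id"] == lesion_id].iterrows()
        ]
        row0 = by_mod["PET"]
        cases.append(
            CohortCase(
                lesion_id=str(lesion_id),
                site=str(row0["site"]),
                lesion_class=str(row0["class"]),
                spect=vols["SPECT"],
                pet=vols["PET"],
                acq_spect=acq_spect,
                acq_pet=acq_pet,
                seed_spect=seed_idx["SPECT"],
                seed_pet=seed_idx["PET"],
                bg_centers_mm=centers,
                truth=truth.get(str(lesion_id), {}),
            )
        )
    return cases
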