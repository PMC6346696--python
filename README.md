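# suvkit

Quantitative SPECT/PET lesion-uptake analysis as a tested, reusable
pipeline: calibrated SUV maps, cross-modality volume-matched lesion
segmentation, SUV_max/SUV_peak/SUV_mean and background-normalized SUVR
extraction, nonparametric agreement statistics, and paired digital-phantom
simulation with known ground truth.

## What it does

Paired bone-imaging studies (e.g. a Tc-99m SPECT scan and an F-18 NaF PET
scan of the same patient) can be compared quantitatively by

1. converting reconstructed volumes into SUV maps — for SPECT via a
   phantom-derived kBq/cps conversion factor, then
   `SUV = concentration (Bq/ml) × weight (g) / decay-corrected injected
   activity (Bq)`;
2. segmenting each lesion in a reference modality (PET, `SUV > 15` by
   default) as the 26-connected component above threshold, then segmenting
   the same lesion in the other modality at the threshold whose VOI volume
   best matches the reference volume;
3. extracting SUV_max (hottest voxel), SUV_peak (maximal mean over a ~1 cm³
   cube centered in the lesion), SUV_mean, a background SUV from the union
   of 1-cm disk ROIs on normal bone, and SUVRs (lesion SUV / background);
4. summarizing paired agreement with least-squares regression,
   nonparametric Bland–Altman (median difference and 2.5th/97.5th
   percentile limits of agreement, relative to SPECT), Wilcoxon
   signed-rank and Mann–Whitney U tests (exact enumeration at small n),
   lesion-size-stratified difference tables, and per-site background
   summaries.

Because no clinical images ship with the package, a first-class simulator
(`suvkit.phantom`) generates paired SPECT-like (4.8 mm isotropic) and
PET-like (3.65 or 5.47 × 3.27 mm) digital phantoms: spherical lesions over
site-dependent bone background, a programmable PET/SPECT uptake ratio,
per-modality Gaussian system blur, signal-scaled noise, and a counts branch
that inverts the calibration path. Every pipeline stage can be validated
against this ground truth.

## CLI

```sh
suvkit simulate  --spec cohort.yaml --seed 7 --out bundle/   # phantom bundle
suvkit calibrate --counts phantom.nii --voi-mask mask.nii \
                 --true-activity-kbq 2140 --out factor.json  # kBq/cps factor
suvkit suv       --volume scan.nii --acq acq.json --out suv.nii
suvkit segment   --suv-volume suv.nii --seeds seeds.csv --out-dir masks/
suvkit metrics   --suv-volume suv.nii --voi-mask masks/L0_pet_mask.nii \
                 --bg-rois bg.csv --out metrics.csv
suvkit analyze   --config run.yaml                           # end to end
suvkit compare   --lesions lesions.csv --out agreement.json --plots plots/
```

A minimal simulation spec is `{n_lesions: 50}`; an `analyze` config needs
`bundle: <simulate output dir>` and optionally `output_dir`, `threshold`
(default 15), `threshold_policy: fixed|relative`, `max_rel_mismatch`
(default 0.20), `reference` (default PET). Volumes are NIfTI-1; seeds and
background-ROI tables are CSV; acquisition records are JSON/YAML with
activities in MBq and ISO-8601 timestamps. Every report carries a
provenance block (config hash, seed, version).

## Conventions worth knowing

- Voxel `(i, j, k)` has its physical center at `(i+0.5, j+0.5, k+0.5) ×
  spacing` (cell-centered grid, origin at the volume corner).
- Count-rate volumes store cps per voxel; Bq/ml conversion divides by the
  voxel volume.
- Thresholding is strictly greater-than; connectivity is 26-neighborhood.
- The SUV_peak cube edge is the nearest integer number of voxels to 10 mm
  per axis (min 1), so its physical volume is only approximately 1 cm³.
- All normalized differences are `100 × (PET − SPECT) / SPECT`, so positive
  medians mean PET reads higher.
- Percentiles interpolate linearly between order statistics at
  `h = (n−1)p + 1`; Wilcoxon drops zero differences before ranking.
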