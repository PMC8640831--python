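# gestaliver

Toolkit for studying gestational liver-volume dynamics: phantom-based
abdominal MRI segmentation, slice-summation liver volumetry with a
measurement-error-aware change classifier, tracer-clamp glucose physiology,
densitometric body composition, weighted assay calibration, and the cohort
statistics stage — all exercisable end to end on synthetic data, with no
external downloads.

## Modules

| module | contents |
|---|---|
| `gestaliver.grids` | `ImageVolume` / `LabelVolume` voxel-grid containers, NIfTI I/O |
| `gestaliver.phantoms` | 2.5D abdominal phantoms with exact tissue ground truth, bias fields, noise; liver ROI slice-stack generator |
| `gestaliver.segmentation` | five-class pipeline: bias-field correction, Otsu adipose thresholding, seeded compact-watershed muscle, peripheral-shell SAT, VAT by subtraction, uterus/liver exclusion masks, axial bounding |
| `gestaliver.volumetrics` | slice-summation volumes, percent change, interoperator variability, gain / no-change / loss classification (default ±7% tolerance), gain-loss pattern labels, station-overlap merging |
| `gestaliver.physiology` | steady-state tracer EGP (basal and insulin-suppressed), Rd, insulin/FFM adjustment, two-compartment densitometry, lipid/water ratios, 1/x-weighted linear calibration |
| `gestaliver.cohort_sim` | synthetic participant-visit cohort with configurable stage means/SDs, a single-factor change-correlation structure, quota-enforced subgroups, postwean completion, hypertension confinement, EGP/Rd group shifts |
| `gestaliver.cohort_stats` | correlation battery with exact p arithmetic, paired t tests, pattern subgroup comparisons, proportion reporting, CSV/Markdown reports |

## CLI

```bash
# phantom with ground truth, bias field, and exclusion masks (NIfTI)
gestaliver phantom --seed 17 --out phantom/

# five-class segmentation of a volume given sparse seed labels
gestaliver segment phantom/image.nii.gz phantom/seeds.nii.gz \
    --uterus phantom/uterus_mask.nii.gz --liver phantom/liver_mask.nii.gz \
    --out seg/

# synthetic cohort and the statistics report
gestaliver simulate --n 47 --seed 1 --out cohort.csv
gestaliver analyze cohort.csv --out report/

# clamp metrics from a CSV of steady-state records
gestaliver clamp clamp_records.csv --out clamp_results.csv

# weighted calibration fit + back-calculation
gestaliver quantify standards.csv samples.csv --out quantified.csv
```

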