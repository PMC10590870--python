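# rimspec

Metabolic profiling of iron-containing multiple-sclerosis lesions from MR
spectroscopic imaging (MRSI), driven end to end by a synthetic phantom
generator so that every stage runs without any data download.

In relapsing-remitting MS, lesions that accumulate iron — visible as
hypointensities on susceptibility-weighted imaging (SWI) — carry more tissue
damage than iron-free lesions, and lesions with a distinct *paramagnetic rim*
are the most damaged subtype. 7 T MRSI makes this damage measurable as
metabolite ratios: tNAA/tCr (neuronal/axonal integrity) falls and mIns/tNAA
(astroglial activation over integrity) rises inside iron-rim lesions, with a
steeper gradient toward the lesion core, and the tNAA deficit of newly
emerging iron lesions persists at one-year follow-up instead of recovering.

`rimspec` implements that analysis as a tested, reusable pipeline:

| module | what it does |
| --- | --- |
| `rimspec.phantom` | seeded synthetic cohorts: tissue/lesion label volumes, metabolite-ratio maps with calibrated group means and radial gradients, SWI-like volumes, 3-timepoint longitudinal series |
| `rimspec.spectral` | linear-combination fitting of complex spectra over 1.8–4.2 ppm (non-negative least squares on a Lorentzian peak basis + macromolecular background) with CRLB%, NAA SNR and NAA FWHM quality maps |
| `rimspec.roi` | tricubic resampling to the anatomical grid, strict >20 mm³ lesion filter, 37 mm³ NAWM reference ROIs ≥5 mm from GM/CSF/lesions, rule-based iron-type classification (rim / area / transition / non-iron) on SWI |
| `rimspec.layers` | seven concentric lesion layers (L+3…L−3) by repeated 3D dilation/erosion, GM/CSF-intrusion exclusion, periphery-normalized layer profiles |
| `rimspec.longitudinal` | detection of newly emerging lesions and evaluation of the fixed Year-0 footprint at Year −1 / Year 0 / Year 1 |
| `rimspec.stats` | descriptives (mean ± SD, n−1), one-way ANOVA, Tukey–Kramer HSD, percent differences, CSV report emission |

## Worked example

Generate a cohort with the default study conditions — 220 lesions with the
published group sizes (174 non-iron, 13 area, 7 transition, 26 rim) spread
over ten subject phantoms plus 40 NAWM reference ROIs — and compare
mIns/tNAA across groups:

```python
import numpy as np
import rimspec as rs
from rimspec.pipeline import generate_cohort, analyze_cohort_rois, roi_group_comparisons
from rimspec.config import INCLUDED_LESION_COUNTS

rng = np.random.default_rng(1)
subjects = generate_cohort(rs.PhantomConfig(), rng,
                           type_counts=INCLUDED_LESION_COUNTS, n_subjects=10)
rois = analyze_cohort_rois(subjects, rng, nawm_rois_per_subject=4)
comps = roi_group_comparisons(rois)
c = comps["mIns/tNAA"]
print(c.table.round(3).to_string(index=False))
print(f"ANOVA F = {c.anova_f:.2f}, p = {c.anova_p:.2g}")
print(f"Tukey rim vs non_iron: p = {c.tukey_p('rim', 'non_iron'):.3f}")
print(f"Tukey rim vs NAWM:     p = {c.tukey_p('rim', 'NAWM'):.2g}")
```

prints

```
     group   n  mean    sd
      NAWM  40 0.565 0.122
  non_iron 174 1.147 0.591
      area  13 0.933 0.175
transition   7 1.129 0.428
       rim  26 1.604 1.321
ANOVA F = 11.28, p = 1.9e-08
Tukey rim vs non_iron: p = 0.008
Tukey rim vs NAWM:     p = 7.7e-09
```

The recovered group means scatter around the configured population values
(rim 1.53, non-iron 1.13, NAWM 0.53 for this ratio), and the analysis
detects the elevation of mIns/tNAA in rim lesions over both non-iron lesions
and normal-appearing white matter — the group structure the pipeline exists
to measure. `rimspec.pipeline.run_full_pipeline` chains the remaining
stages (MRSI synthesis + fitting, layer profiling, longitudinal tracking,
CSV report) in one call.

A command-line interface mirrors the library:

```sh
rimspec simulate --out phantom/ --seed 1          # NIfTI volumes + ground truth CSV
rimspec rois --labels phantom/labels.nii.gz --maps phantom/ \
             --swi phantom/swi.nii.gz --out rois.csv
rimspec layers --labels phantom/labels.nii.gz --maps phantom/ \
               --swi phantom/swi.nii.gz --out layers.csv
rimspec report --rois rois.csv --out report/
```

## Scope

The package starts from spectra/maps and synthetic anatomy: scanner
acquisition, k-space reconstruction (coil combination, parallel-imaging
unaliasing, lipid removal) and manual segmentation are out of scope, and
the spherical-lesion phantom makes no claim of anatomical realism — every
downstream operator consumes only masks and voxel values. See
`docs/methods.md` for the model, its assumptions and known limitations.
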