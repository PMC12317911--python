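# batcsi

Water-to-oil ratio analysis of periprostatic adipose tissue on chemical-shift
(DIXON) MRI, aimed at detecting brown-fat signal and using it — together with
serum iPSA — for prostate-cancer risk stratification. Because no patient data
are deposited, the package ships a synthetic phantom cohort generator that
reproduces the statistical structure the analysis assumes.

## What it does

- **`batcsi.core`** — per-slice image computations: 12-bit → 8-bit display
  conversion (affine rescale, round-half-up), elementwise water/fat ratio
  with an explicit zero-fat policy, ROI (annulus) masking, top-1% extraction
  of the largest ratio elements, image rendering and RGB contour overlays.
- **`batcsi.phantom`** — synthetic DIXON-like slice pairs (prostate ellipse,
  periprostatic fat annulus, sparse brown-fat blobs with a higher
  water-to-fat ratio), log-normal iPSA draws moment-matched to per-group
  mean/SD, and fully seeded cohort generation (default group sizes 4/4/13).
- **`batcsi.stats`** — per-patient pooled summaries, Welch t / Mann-Whitney
  group comparison, ROC curves with trapezoidal AUC, a logistic combination
  of log iPSA and the imaging feature, and stratified bootstrap AUC
  uncertainty.
- **`batcsi.io` / `batcsi.pipeline` / `batcsi.cli`** — CSV / 16-bit PNG /
  TIFF readers (DICOM optional via the `dicom` extra), mask contour tracing,
  a config-driven end-to-end pipeline and a CLI.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (conversion level
count, elementwise-oracle equivalence of the ratio and extraction steps,
AUC↔concordance equivalence, binormal closed-form AUC recovery, and phantom
cohort parameter recovery over 20 seeds).

## CLI

```bash
# generate the default 21-patient synthetic cohort as plain CSV matrices
batcsi simulate --out runs/sim --seed 7

# run the full analysis: per-slice images, summaries, comparisons, ROC
batcsi analyze --manifest runs/sim/manifest.csv \
               --clinical runs/sim/clinical.csv \
               --out runs/analysis --seed 7

# single slice → display images + statistics
batcsi slice --water w.csv --fat f.csv --mask m.csv --out runs/slice

# recompute comparisons/ROC from saved patient summaries
batcsi report --summaries runs/analysis/patient_summaries.csv --out runs/rep
```

`analyze` writes `patient_summaries.csv`, `group_stats.csv`,
`group_comparison.csv`, `roc_results.csv` (with curve points),
`slice_stats.csv`, `roc_curves.png`, a plain-text report, and a
`run_manifest.json` recording the config hash and seed. Reruns with the same
config reproduce all numeric CSVs bitwise. A YAML/JSON config file can
replace the flags (`batcsi analyze --config config.yaml`).

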