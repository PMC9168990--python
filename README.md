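# glycomig

Serum IgG Fc N-glycopeptide profiling from linear-mode MALDI-TOF spectra,
with a feedforward-network case/control classifier. The package covers the
full analysis chain:

- **glycolib** — glycoform shorthand algebra (`G0F`, `G2S2`, `G0-NF`, …),
  subclass peptide backbones (IgG1 `EEQYNSTYR`, IgG2 `EEQFNSTFR`, isomeric
  IgG3/4 treated as one class), theoretical monoisotopic [M+H]+ masses, and
  the annotated 22 × 3 glycopeptide library with isobaric-overlap flags.
- **spectra** — two-column text (optional mzML) ingest, morphological
  top-hat baseline subtraction, threshold peak picking with parabolic apex
  interpolation, m/z windowing, and affine internal calibration against
  four theoretical calibrant masses.
- **quantify** — peak-to-library assignment (missing → 0), relative
  intensities normalized to the profile sum, technical-replicate averaging,
  and RSD repeatability QC at six reference masses.
- **traits** — derived glycan traits (bisecting GlcNAc, fucosylation splits,
  sialylation, G0/G1/G2 aggregates, Gal-ratio `G0/(G1 + 2·G2)`).
- **cohortstats** — pooled two-tailed Student's t-tests, Pearson chi-square
  for 2×2 tables (no continuity correction), ANOVA-F feature ranking,
  optional Benjamini–Hochberg adjustment.
- **classifier** — the 7-6-4-2 sigmoid/softmax feedforward network with
  min-max scaling, full-batch gradient-descent training, Mann–Whitney
  ROC/AUC, and stratified 5-fold cross-validation. Scaling and feature
  selection are fit inside each training fold by default; `--paper-mode`
  fits them once on the full dataset (leaky, for protocol comparison).
- **synthcohort** — synthetic cohorts (20+20 by default, with aura /
  ictal-phase / family-history subgroups) via logistic-normal perturbation
  of a template profile, plus linear-mode spectrum synthesis (Gaussian
  peaks, baseline drift, noise, affine mass error, replicate CV).

## CLI

```bash
glycomig library  --out library.csv
glycomig simulate --out simdir/ --seed 7
glycomig process  --manifest simdir/manifest.csv --out profiles.csv --window 2400:3500
glycomig traits   --profiles profiles.csv --out traits.csv --scope total
glycomig stats    --profiles profiles.csv --manifest simdir/manifest.csv --out stats.csv
glycomig crossval --features profiles.csv --labels simdir/manifest.csv --k 7 --seed 7 --out cv.json
glycomig train    --features profiles.csv --labels simdir/manifest.csv --k 7 --seed 7 --out model.json
glycomig predict  --model model.json --features profiles.csv --out preds.csv
glycomig pipeline --manifest simdir/manifest.csv --out rundir/
```

The manifest is a CSV with columns `sample_id, group, aura, ictal,
family_history, age, sex, replicate_paths` (semicolon-separated spectrum
paths relative to the manifest). Spectrum files are two-column
`m/z intensity` text with `#` comments. Processing defaults: 0.050 mV peak
threshold, 20 Da top-hat window, 2450–3500 export window (widen to
2400 for synthetic cohorts so the low-mass `IgG1 G0-NF` peak at ~2431 is
retained), 1.5 Da calibrant match tolerance, 1.0 Da assignment tolerance.

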