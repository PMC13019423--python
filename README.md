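# evspec

Chemometric analysis of AFM-IR nanospectra of extracellular vesicles (EVs).

Blood-derived EVs carry cell-type-specific molecular signatures, but what an
infrared spectrum of "an EV" looks like depends strongly on how the vesicles
were isolated.  This package implements the full analysis chain used to
compare three isolation methods — size-exclusion chromatography (SEC), Total
Exosome Isolation Reagent (TEIR, polymer precipitation), and differential
ultracentrifugation (UC) — from single-particle AFM-IR spectra in the
950–1920 cm⁻¹ fingerprint window:

* **Synthetic spectrum generator** — pseudo-Voigt band models built from the
  published mid-IR assignment table for each isolation method, with an
  albumin-corona contribution, particle-to-particle amplitude jitter,
  wavenumber-calibration drift, polynomial baselines, noise, and a small
  fraction of albumin-dominated bioaggregate "particles".  No real spectra
  are distributed with this package; the generator provides statistically
  faithful surrogates so that every stage is testable.
* **Outlier QC** — PCA with reduced Hotelling T² (score outliers) and reduced
  Q residuals (off-model outliers); a sample is discarded when either
  statistic exceeds its 95% confidence limit (T²: F-distribution limit,
  Q: Jackson–Mudholkar).
* **Preprocessing** — iterative modified-polyfit baseline correction
  (least-squares polynomial, points above the fit clamped to it, repeated to
  convergence) followed by total-intensity normalisation.
* **Unsupervised analysis** — PCA score/biplot tables, leave-one-out
  nearest-centroid discrimination in the PC1–PC2 plane, Ward hierarchical
  clustering with a k-cluster cut scored by label purity.
* **PLS-DA** — NIPALS PLS2 regression on one-hot class membership,
  leave-one-out cross-validation for the component count, label-permutation
  testing (the permuted fits re-select their own component count), VIP
  scores (Σ VIP² = p) and coefficient-based importance.
* **Albumin deconvolution** — the albumin reference spectrum fitted as a sum
  of pseudo-Voigt bands, scaled into each group-average EV spectrum by
  nonnegative unmixing against the assignment-table band positions, and
  subtracted to estimate the pure EV spectrum.
* **Power analysis** — resampling stability of classification accuracy
  versus particles-per-group, and empirical power of the permutation test.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
calibrated synthetic profile (3 methods × 40 particles, seed 17) and write
their tables under `results/`:

```bash
python analysis/01_generate_spectra.py      # raw spectra + ground truth
python analysis/02_outlier_qc.py            # T²/Q report, survivors
python analysis/03_preprocess.py            # baseline + normalisation
python analysis/04_multivariate.py          # PCA, biplot bands, dendrogram
python analysis/05_plsda.py                 # PLS-DA + permutation test
python analysis/06_albumin_deconvolution.py # albumin removal per group
python analysis/07_power_analysis.py        # stability + power (slow, ~3 min)
```

Output of the core steps on this profile:

```
flagged 17 of 120 particles (14%); 103 survive
PC1-PC2 LOO nearest-centroid discrimination: 99.0%
Ward cut at k=3: majorities {0: 'TEIR', 1: 'UC', 2: 'SEC'}, purity 100.0%
PLS-DA (2 components by LOO-CV): accuracy 100.0%, R2 0.927, Q2 0.917
permutation test (999 shuffles): p = 0.0010
highest VIP wavenumbers: 978, 976, 974, 980, 1034 cm-1
```

The QC stage removes particles whose raw spectra sit outside the PCA model
(calibration-drift tails and albumin-dominated aggregates).  The two
discriminant regions recovered by both the biplot and the VIP profile — the
O–P–O symmetric phosphate stretch near 977 cm⁻¹ and the glycosidic-linkage
band near 1035 cm⁻¹ — are exactly where the generator plants the
between-method intensity differences, mirroring where the real study found
its discrimination.  The permutation p of 0.001 is the smallest value
attainable with 999 shuffles, i.e. no permuted labelling matched the
observed accuracy.

The same pipeline is scriptable from the shell (`evspec --help`):

```bash
evspec generate --seed 17 raw.csv
evspec qc raw.csv qc.csv --survivors surv.csv
evspec preprocess surv.csv pre.csv
evspec plsda pre.csv --n-perm 999 --seed 17 --out perf.json --vip vip.csv
```

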