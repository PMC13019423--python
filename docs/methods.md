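# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `evspec` pipeline.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The spectral model

Every spectrum lives on a shared wavenumber axis, by default 950–1920 cm⁻¹
at 2 cm⁻¹ — the fingerprint window of a quantum-cascade-laser AFM-IR
instrument.  Bands are pseudo-Voigt profiles in the standard η
parameterisation: a linear mixture `amp·[η·L(x) + (1−η)·G(x)]` of a
Lorentzian and a Gaussian that share one centre and one FWHM, each with unit
peak height, so `amp` is the peak intensity regardless of η.  Default band
width is 18 cm⁻¹ with η = 0.5, which makes neighbouring assignment-table
bands partially overlap, as in real bio-IR spectra.

## Synthetic data generator

No single-particle EV spectra are distributed with the package, so the
generator is a first-class, tested module that emulates the statistical
structure the downstream chemometrics assumes.  Each simulated particle is

```
ev_scale · Σ_b jitter_b · amp_b · PV_b(x − δ)       (method band template)
  + f · albumin(x − δ)                              (corona contribution)
  + polynomial baseline + white noise
```

* **Band templates** come row-for-row from the packaged mid-IR assignment
  table (AFM-IR columns per isolation method); range entries (e.g.
  1550–1575 cm⁻¹) are placed at the range midpoint.  Default amplitudes are
  set per assignment family (Amide I strongest, fingerprint bands weaker).
* **Planted discrimination.**  Between-method intensity contrasts are
  concentrated at the O–P–O symmetric phosphate stretch (977/978/982 cm⁻¹;
  amplitudes TEIR 2.6, UC 1.3, SEC 0.3) and the glycosidic-linkage band
  (1035/1038 cm⁻¹; 2.3/1.3/0.35).  SEC is depleted at both (consistent with
  its aggressive removal of co-isolated material), UC intermediate, TEIR
  highest.  These two windows dominate the between-group variance of the
  generated data, so a correct implementation of PCA-biplot ranking and VIP
  scoring must recover them.
* **Albumin corona.**  The albumin reference is four bands — Amide I
  1650 cm⁻¹ (amplitude 2.5, FWHM 42), Amide II 1550 (1.7, 38), CH₂/CH₃
  scissoring 1450 (0.7, 30), υPO₂⁻/PBS 1070 (0.9, 34).  Per-particle corona
  weights are Gaussian with means 0.27 (TEIR), 0.31 (UC), 0.20 (SEC) and
  spreads 0.10/0.14/0.08, clipped to [0, 0.95].
* **Heterogeneity.**  Band amplitudes get multiplicative log-normal jitter
  with CV 0.20 (TEIR, SEC) and 0.35 (UC — ultracentrifugation pellets are
  the most heterogeneous).  Each particle additionally receives a rigid
  wavenumber shift δ ~ N(0, 3 cm⁻¹) applied to every band centre, emulating
  QCL calibration drift and local-environment peak shifts.  This drift is
  the main reason classification accuracy stays below 1: it blurs the
  band-position differences between the method templates, which would
  otherwise make the 486-channel classes perfectly separable at any
  realistic noise level.
* **Bioaggregates.**  With probability 0.04 a "particle" is an
  albumin-dominated bioaggregate rather than a clean EV: its EV pattern is
  attenuated by a factor U(0.1, 0.4), its albumin weight drawn from
  U(0.5, 0.8), and it carries an intermolecular β-sheet aggregation band at
  1622 cm⁻¹ scaled with the albumin load.  Rates much above this let the
  aggregates of all three groups coalesce into their own cluster under Ward
  linkage, destroying the three-method dendrogram structure; 4% keeps the
  clouds unimodal.
* **Baseline and noise.**  Degree-3 polynomial with coefficients uniform on
  ±0.15 (on a [−1, 1]-scaled axis), plus i.i.d. Gaussian noise of SD 0.08 —
  roughly 3–10% of typical band heights.

These constants were calibrated once so that the full pipeline reproduces
the study-level outcomes (≈ 93% or better LOO-CV PLS-DA accuracy, > 90%
PC1–PC2 discrimination, a clean three-cluster dendrogram, > 80% power at 30
particles per group, accuracy stabilising by 30 per group) robustly across
seeds, and are frozen in the packaged defaults.  A null variant shares one
template, one corona distribution and one jitter level across all groups;
it is used to calibrate the type-I error of the permutation machinery.

**What the generator does not model:** photothermal tip–sample mechanics,
wavelength-dependent detector response, correlated (pink) noise, scattering
artifacts, PBS crystal bands, or instrument-grid differences between
particles (all rows share one axis; real data on differing grids must be
resampled at I/O time).  Passing tests therefore demonstrate correctness of
the chemometrics on band-structured spectra with realistic heterogeneity —
not performance on any particular instrument's artifacts.

## Outlier QC

QC runs on mean-centered **raw** spectra, before baseline correction — the
workflow this package mirrors removes outliers first and preprocesses the
survivors, so the QC statistics see the spectra as measured.  The PCA model
retains the smallest number of components explaining ≥ 90% of variance,
capped at 10.  Hotelling T² (scores weighted by inverse eigenvalue) is
divided by its 95% limit `A(n−1)/(n−A)·F₀.₉₅(A, n−A)`; the Q residual
(squared off-model distance) by the Jackson–Mudholkar limit built from the
discarded eigenvalues (normal approximation; a log-normal fallback covers
degenerate h₀ ≤ 0).  "Reduced" means statistic/limit, so 1 is the decision
boundary in both coordinates.  The default flag rule is the union (either
statistic above 1); intersection is available.  On in-model Gaussian data
each statistic flags ≈ 5% of samples, which the suite verifies by
simulation.  On the calibrated profile the union rule removes 10–17% of
particles — drift tails and the more extreme bioaggregates.

## Preprocessing

Baseline correction is the iterative modified polyfit: fit a least-squares
polynomial (default order 5) to the working spectrum, clamp every working
value above the fit down to it, refit, and stop when the fit moves by less
than `tol` (default 10⁻⁶ of the row's peak intensity) or after `max_iter`
iterations.  Order 5 removes the generator's degree-3 drift with margin
while not swallowing the broad Amide bands; the fit is computed on a
[−1, 1]-scaled axis via a QR-orthogonalised Vandermonde basis, and whole
matrices are processed in one vectorised loop.

Two properties of this iteration deserve explicit documentation:

* At convergence the baseline never exceeds the raw spectrum (the clamp
  admits no upward pressure), which is the invariant the suite asserts.
* For the same reason, polynomial wiggle induced by strong peaks in the
  first pass is locked in, so the converged baseline sits slightly *below*
  the true background and peak areas measured on the corrected spectrum are
  over-estimated (tens of percent for a single strong band on a ramp).
  `guard="std"` switches to the improved variant that clips against
  `fit + std(residual)`: band areas then come out nearly unbiased, but the
  baseline may ride above the raw signal inside noise, so the
  baseline-below-raw invariant does not apply to it.  The pipeline default
  is the plain clamp; the guarded variant is for quantitative band-area
  work.

Normalisation divides each spectrum by its summed absolute intensity (the
absolute value makes the normaliser strictly positive despite small
negative post-baseline values).  Mean-centering is applied inside PCA/PLS,
never persisted to files.

## PLS-DA

Class membership is coded one-hot (class order = first appearance; argmax
decision, ties to the earliest class).  The fit is NIPALS PLS2 with
deflation of X only, computed at the exact fixed point of the NIPALS inner
loop: each component's weight vector is `w ∝ XᵀY·q` with `q` the dominant
eigenvector of the g×g matrix `(XᵀY)ᵀ(XᵀY)` — what the power iteration
converges to, obtained directly.  Weight signs are fixed so each vector's
largest-magnitude entry is positive.  Regression coefficients are assembled
through the rotation matrix `R = W(PᵀW)⁻¹`.

Leave-one-out CV evaluates all component counts 1..A_max in one fitted
model per fold (nested models share leading components).  The fold loop
runs in the kernel (Gram-matrix) dual form: with K = XXᵀ computed once,
every per-fold operation — double-centering, component extraction, X
deflation, held-out scoring — is O(n²) instead of O(n·p), and the inner
loop is JIT-compiled (a pure-numpy fallback produces identical numbers and
is asserted equivalent in the suite, as is agreement with scikit-learn's
NIPALS implementation to 10⁻⁶).  The optimal component count is the
smallest one maximising LOO accuracy; Q²(A) = 1 − PRESS(A)/TSS with TSS
from the full-data centered response.

The permutation test shuffles the labels, **re-selects the component count
by LOO for every permutation** (so the null distribution carries the same
selection optimism as the observed statistic), and reports the add-one
p-value `(1 + #{perm ≥ obs})/(1 + n_perm)`; its floor is 1/(n_perm+1).
Accuracy is a coarse statistic: at small n, ties between permuted and
observed accuracies make the test conservative (measured rejection ≈ 0.02
at 15 particles per group under the null).  The type-I calibration in the
acceptance suite therefore runs at 25 per group, where the rejection rate
matches α.

VIP scores use the standard weighted-sum-of-squares form
`VIP_j = sqrt(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with SSY the
response variance explained per component; Σ VIP² = p exactly.
Coefficient importance is the per-class squared regression coefficient,
normalised by the component count and averaged over classes.

## Unsupervised analysis

"% discrimination" for a PC pair is operationalised as leave-one-out
nearest-centroid accuracy in that score plane — deterministic and monotone
in class separation; this is a package definition, since the quantity has
no standard operational form.  Hierarchical clustering defaults to Ward
linkage on Euclidean distances over preprocessed spectra (raw spectra or
PC scores are selectable); the k-cluster cut undoes the last k−1 merges,
and purity is the fraction of samples whose cluster's majority label
matches their own.  Dendrograms serialise to Newick with merge heights as
branch lengths.

## Albumin deconvolution

The albumin reference spectrum is fitted as a sum of pseudo-Voigt bands by
bounded trust-region least squares (centres within ±10 cm⁻¹ of
initialisation, FWHM 2–200 cm⁻¹, η ∈ [0,1], amplitudes ≥ 0; initial bands
from peak picking or the packaged albumin positions).  The fitted shapes
are then held fixed and scaled into each group-average EV spectrum by
nonnegative least squares.

A plain NNLS of the sample onto the albumin bands alone systematically
over-attributes: genuine EV Amide I/II intensity overlaps the albumin bands
and is absorbed into the "contamination".  The projection therefore
competes the albumin model against unit-amplitude bands at every pooled
AFM-IR assignment-table position (joint nonnegative unmixing), and reports
only the albumin part.  With this basis, a sample that *is* the fitted
albumin model still returns unit scales exactly (the exact solution is the
unique zero-residual minimiser), an albumin-free EV spectrum returns ≈ 0,
and the recovered albumin share of a synthetic mixture is accurate to a few
percent — all asserted in the suite.  Per-band scaling is the default
("adjusting" the contribution band by band, since corona conformation
shifts band ratios); a single global multiplier is available as
`scale_mode="global"`.  Subtraction satisfies
`ev_estimate + contribution = sample` identically.

## Power analysis

The replicate source is either the calibrated generator (fresh draws —
unbiased, the default) or an existing dataset (subsampling without
replacement).  Each replicate runs preprocess → LOO-CV; the stability curve
reports mean ± SD accuracy per grid point (default n ∈ {10, 20, 30, 40},
50 replicates), and the stabilisation n is the smallest grid point within
0.02 of the largest-n mean.  Empirical power is the fraction of replicates
whose permutation test (199 shuffles in the loops, vs 999 for one-shot
analyses) rejects at α = 0.05.  Power loops search at most 5 PLS components
— the LOO-selected count on these data is 2–3, and the reduced search keeps
50 replicates × 200 permutation fits desk-scale (a few minutes on one CPU).

## Numerical and degenerate-input conventions

* PCA via SVD of the centered matrix; eigenvalues with divisor n−1;
  loading signs fixed as in PLS.  Component counts are validated against
  min(n−1, p).
* Rank exhaustion during PLS extraction stops early and carries the last
  nested prediction forward; a zero-variance X or zero X–Y covariance is an
  error.
* Zero-intensity spectra: normalisation raises; the baseline of an all-zero
  spectrum converges to zero in one pass.
* All stochastic stages take explicit integer seeds; identical config and
  seed give bit-identical outputs, which the suite asserts.

## Known limitations

* The generator is phenomenological; none of its magnitudes (band widths,
  noise, jitter, corona weights) are measured values, and conclusions about
  real instruments do not follow from passing tests.
* The accuracy-based permutation test is conservative at small n (see
  above); a finer statistic (e.g. mean margin) would calibrate at smaller
  samples but is not what the mirrored workflow uses.
* Deconvolution removes a single named reference; multi-contaminant blind
  source separation is out of scope.
* No instrument-native file formats (JCAMP-DX, Bruker/Anasys) in this
  version; interchange is delimited text.
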