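# Methods

## The GFC statistic

Global-brain functional connectivity assigns each gray-matter voxel the
mean Pearson correlation between its BOLD time series and the series of
every other voxel in the mask, Fisher z-transformed.  Two conventions
exist for where the transform is applied; both are implemented:

* `z_of_mean_r` (default): `z_i = artanh(mean_{j≠i} r_ij)`.  This
  matches the natural reading of "average the correlations, then
  transform", and admits an exact fast path: with each masked series
  standardized to zero mean and unit L2 norm (`u_i`), the row sums of
  the correlation matrix are `u_i · S` with `S = Σ_j u_j`, so the map
  costs O(V·T) instead of O(V²·T).  The self-correlation (exactly 1) is
  removed by subtraction.
* `mean_of_z`: `z_i = mean_{j≠i} artanh(r_ij)`, computed in voxel
  blocks to bound memory at O(block · V).

The chosen convention is recorded in each map's JSON sidecar.  For weak
correlations (|r| ≤ 0.1) the two agree to ~1e-2 (artanh is locally
linear); tests assert both against an independent brute-force all-pairs
implementation at 1e-10.

Correlations are clamped to ±(1 − 1e-7) before `artanh` so degenerate
perfect correlations produce large finite values storable in NIfTI.
Voxels with temporal variance below 1e-12 are rejected with an error
listing their positions; `drop_constant_voxels` shrinks the mask
instead when that is the intended handling.  Negative correlations are
averaged in signed form — no rectification, no positive-only variant.

The gray-matter mask keeps voxels whose probability **strictly
exceeds** the threshold (default 0.2), ordered row-major so value
vectors are reproducibly indexed.

Minimal preprocessing (per-voxel linear detrend → least-squares removal
of the 6 rigid-body motion regressors → ideal Fourier-mask band-pass)
is provided as an opt-in convenience and is off by default: the
pipeline's canonical input is already-preprocessed data.

## Motion quality control

Framewise displacement is the Power-style scalar
`FD_t = Σ|Δd| + R · Σ|Δθ|` (translations in mm; rotations in radians
converted to arc length on a sphere of radius R = 50 mm; FD_1 = 0).
Subjects are excluded wholesale — no frame censoring — when
mean FD > 0.2 mm, or any |translation| > 2 mm, or any |rotation| > 2°.
These limits are configurable; they follow common practice since no
single standard exists.  Rotation columns in motion files are read as
radians (SPM convention); degree input requires an explicit flag —
units are never guessed.  Mean FD enters the group model as a nuisance
covariate.

## Group inference

Per voxel, GFC is regressed by OLS on
`[intercept, group (patient=1), age, sex, education, mean FD]` with
continuous covariates mean-centered and sex as a 0/1 indicator; the
group contrast is tested two-sided with dof = n − p.  With no
covariates this reduces exactly to the pooled-variance two-sample t
test (asserted to 1e-10).  Voxels with zero residual variance and zero
contrast estimate are defined to have t = 0.

Family-wise error is controlled by default with a **Freedman–Lane maxT
permutation**: the nuisance-only fit is removed, its residuals are
row-permuted (the identity permutation is always included so the
observed statistic is a member of its own null), the full model is
refit, and the maximum |t| over the mask recorded; the corrected
threshold is the order statistic `ceil((1−α)·n_perm)` of that null.
This is chosen over Gaussian-random-field correction because it is
exact at any smoothness and grid size, with no smoothness estimation;
Bonferroni is available as a fast fallback.  No cluster-extent
threshold is applied — voxel-level correction alone defines
significance.  Significant voxels are grouped into 26-connected
components (6/18 available), split by the sign of t, with the peak
voxel (max |t|, row-major tie-break) mapped to MNI mm through the
affine.

## Clinical correlations and classification

Per-subject mean z over each cluster is screened against clinical
variables with Pearson correlation among patients (the clinical
variables exist only for them), missing values dropped pairwise, never
imputed.  The Bonferroni family defaults to all (cluster × variable)
tests actually performed; a per-cluster family is available, and both
the uncorrected p and the applied threshold are always reported so
either reading can be reproduced.  Normality of the cluster means
(Shapiro–Wilk) is reported but never gates the analysis.

Classification evaluates each cluster mean alone with an RBF-kernel SVM
under leave-one-out cross-validation, features standardized with
training-fold statistics only.  By default hyperparameters
(C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1, 10}) are selected per outer
fold by an inner leave-one-out grid search (nested, unbiased).  The
non-nested mode selects (C, γ) by the same LOOCV whose accuracy is
reported — it reproduces the optimistic historical practice and
therefore carries an explicit leakage warning in its report.  Because
clusters are defined on the same subjects that are then classified,
every report flags this selection circularity.

**LOOCV null behaviour.**  Under permuted labels, plain LOOCV with a
flexible classifier is *pessimistically* biased: the held-out subject's
class is underrepresented in its training fold, so accuracy falls
measurably below the majority-class rate (~45% vs 52.8% in our
simulations).  A strongly regularised SVM (C = 0.1, γ = 0.01) collapses
to the training-majority predictor, whose LOOCV accuracy equals the
majority-class rate exactly under any labelling; the permutation-null
sanity check therefore uses that configuration, and separately asserts
the flexible configuration shows no *optimistic* bias.

## The synthetic cohort

The generator emulates exactly the structure the analysis assumes, with
ground truth exposed for recovery testing:

* 4D BOLD per subject on a 16³ grid (3 mm isotropic, MNI-like affine),
  150 frames at TR 2 s — large enough for spatial clustering, small
  enough for seconds-scale tests;
* spatially smoothed Gaussian noise (FWHM 2 voxels) so the permutation
  machinery faces realistic spatial autocorrelation — white noise would
  make FWE trivially conservative;
* one shared latent "global" time series (normalised to unit sample
  variance so the drawn coupling is the exact realised amplitude) added
  to a spherical hub with per-subject coupling
  ~ Normal(group mean, 0.10) truncated at 0; defaults
  coupling_patient = 0.25, coupling_control = 0.05;
* a centered-ball gray-matter probability map with the configured
  fraction (0.55) strictly above the 0.2 threshold;
* near-zero random-walk motion traces, with a configurable number of
  subjects **per group** given large-amplitude motion that violates the
  default exclusion limits (the enrolled-cohort default 38 + 40 with 3
  high-motion per group reproduces the canonical 35 + 37 analysed
  sample);
* clinical variables built as `x = r·ĉ + sqrt(1−r²)·ε` against the
  standardized true coupling ĉ, then affinely rescaled to realistic
  means/sds (e.g. TG 1.06 ± 0.92 mmol/L) — affine, so the planted
  correlation is preserved exactly in expectation.  Values are plain
  Gaussians on that scale; no truncation or folding, which would
  distort the planted correlation for low-mean variables.  Default
  planted effects: TG +0.45, LDL-C +0.42, RBANS coding −0.40, Stroop
  color −0.47; all other variables null.

One integer seed feeds a `SeedSequence` fan-out (gm map, couplings,
clinical noise, per-subject streams), so identical specs give
bit-identical volumes, traces and tables — including the gzipped NIfTI
bytes.

**Calibration of the planted effect.**  Adding an independent latent to
hub voxels *dilutes* their correlations with smoothed-noise neighbours;
the net GFC gain of a hub voxel scales with
(n_hub − k) · c²/(c² + σ²) / V, where k ≈ 27 is the smoothing kernel's
correlation mass.  A hub must therefore be comfortably larger than the
kernel footprint to carry signal: the default hub radius is 3.5 voxels
(179 voxels).  At the defaults the powered 35 + 37 cohort yields a
single positive cluster with peak t ≈ 5.5–9.5, Dice ≥ 0.9 against the
planted hub in most seeds, and a measured hub-GFC/coupling correlation
of ~0.87, so the planted clinical correlation of 0.45 is recovered
attenuated to ~0.39 on average — inside its Fisher-z 95% CI in ≥ 90% of
seeds at n = 35.

**What the generator does not model** — hemodynamic response shape,
physiological (cardiac/respiratory) noise, multi-site effects,
anatomically realistic gray-matter geometry, more than one latent
network, or any coupling between head motion and the BOLD signal.
Passing recovery tests therefore demonstrates the *statistical
machinery* is correct and calibrated, not that the pipeline is robust
to every artefact of real scanner data.

## Problem sizes and determinism

Simulation-based tests use the 16³ default grid: null FWE calibration
over 40 seeds at 1000 permutations, hub recovery and correlation
recovery over 20 seeds each — sizes chosen to keep the whole suite in
single-digit minutes while leaving the binomial acceptance envelopes
meaningful.  The pipeline fans one global seed into per-stage seeds by
hashing the stage name (sha256, reduced below 2³¹), so each stage is
independently reproducible; rerunning any stage with the same config
and seed reproduces its outputs byte-for-byte on one platform.

## Known limitations

* The permutation scheme assumes exchangeable residuals under the
  nuisance model; heteroscedastic groups are not specially handled.
* `mean_of_z` has no O(V·T) fast path; it is block-quadratic.
* The classifier operates on single cluster means; joint multi-region
  classification exists in the API but is not the default and is not
  tuned.
* Cluster anatomical labelling (naming regions) is out of scope; peaks
  are reported as MNI coordinates only.
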