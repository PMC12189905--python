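# Methods

`rehodyn` implements a resting-state fMRI local-synchronisation analysis:
static regional homogeneity (ReHo), its sliding-window temporal variability
(dynamic ReHo), mass-univariate group inference with cluster-level
correction, and a clinical layer (ROI correlations, logistic/ROC
classification). A synthetic-cohort generator supplies ground truth so the
whole chain is testable at desk scale. This note records the models, the
parameters that matter, and the design choices that were genuinely open.

## Preprocessing

The pipeline assumes BOLD data already on a common voxel grid; spatial
steps (slice timing, realignment, coregistration, normalisation,
segmentation) are out of scope. The in-scope chain runs in a fixed order:

1. **Volume discard** — the first 10 volumes are dropped (T1
   equilibration); 240 acquired volumes leave 230 for analysis.
2. **Nuisance regression** — voxelwise OLS against an intercept, a linear
   trend, white-matter and CSF mean signals (supplied as regressor
   columns), and the Friston-24 motion expansion (6 rigid-body parameters,
   their one-volume lag, and both sets squared). Residuals are exactly
   orthogonal to every regressor; rank-deficient confound matrices are
   pruned by pivoted QR with a logged warning.
3. **Bandpass** — an ideal FFT-domain filter retaining 0.01–0.08 Hz.
   Frequency-domain masking (the REST/DPABI convention) was chosen over a
   Butterworth design because it is idempotent and has exact passband
   edges, which makes the filter directly verifiable; the trade-off is
   ringing for broadband transients, irrelevant for the narrowband signals
   analysed here.

Head motion is quantified by the Jenkinson framewise displacement: for
each volume transition the RMS displacement of a solid sphere (default
radius 50 mm, configurable — the algorithm's radius is a free parameter)
under the relative rigid-body transform, in closed form
`sqrt((R^2/5) tr(A'A) + b'b)`. Exclusion uses strict inequalities
("exceeding" read literally): translation > 1.5 mm per axis, rotation
> 1.5 degrees, or mean FD > 0.2. Whether the 1.5 mm criterion is per-axis
or Euclidean is not standardised; per-axis maximum is the default.
Rotations in `rp_*.txt` files are radians (SPM convention) and converted
to degrees internally for the threshold.

## Static ReHo

For each in-mask voxel, Kendall's coefficient of concordance W is computed
over the 27-voxel cube centred on it (the standard ReHo neighbourhood —
"27 adjacent voxels" is read as the cube *including* the centre, not 28
series). With K in-mask member series of length n, ranked over time with
midranks for ties:

    S = sum_t (R_t - K(n+1)/2)^2
    W = 12 S / (K^2 (n^3 - n) - K sum_j T_j),   T_j = sum_ties (t^3 - t)

W is in [0, 1] and invariant to monotone transforms of any series.
Filtered float data essentially never ties, so the tie-corrected path is
exercised mainly by integer-valued synthetic fixtures; both paths are
exact. Voxels whose neighbourhood has fewer than `min_in_mask` (default 2)
in-mask members, or whose member series are all constant, are flagged NaN
— never silently zero.

Standardisation defaults to the Fisher r-to-z transform `z = atanh(W)`
with W clipped at 1 − 1e-7 (clipping is logged). Whether the upstream
tooling's "Fisher r-to-z" means atanh or mean/SD z-scoring is ambiguous;
both are implemented (`method="fisher"` / `"zscore"`) and atanh is the
default, following the transform's name. Smoothing is a separable
Gaussian, sigma = FWHM/(2 sqrt(2 ln 2)) per axis, default 6 mm FWHM,
applied *after* ReHo and standardisation (smoothing never precedes the
concordance computation). Within a mask, kernel weights are renormalised
over in-mask voxels so constants are preserved and undefined voxels do
not bleed in.

## Dynamic ReHo

The series is cut into rectangular sliding windows, default length 50 TRs
(100 s at TR 2 s) and step 5 TRs, giving floor((T−L)/S)+1 windows — 37
for 230 time points. The window must be longer than the period of the
slowest passband frequency (1/0.01 Hz = 100 s); a violation only warns,
since the check depends on the passband actually used. Static ReHo is
computed per window with the same neighbourhood and tie conventions, and
each voxel's dynamic ReHo is the coefficient of variation of its window
series x_t:

    CV = sqrt( (1/n) sum_t (x_t - x_mean)^2 ) / x_mean

The SD is the population form (divide by n, exactly as the definition is
written) and x_t is the raw W, not its Fisher transform (a flag enables
CV on transformed values for sensitivity analyses). Voxels with
non-positive window-mean ReHo are flagged undefined. CV maps are
z-standardised over the mask (population SD) and smoothed like the static
maps.

Note an intrinsic property of the CV: it inherits an inverse dependence
on the mean, so regions whose *static* synchronisation differs between
groups also shift in CV. Interpretation of dynamic contrasts should keep
this coupling in mind; the effect-recovery simulations below therefore
inject static and dynamic effects in separate cohorts.

## Group inference

Per-subject standardised maps enter a voxelwise OLS GLM with intercept,
a 0/1 patient indicator, and mean-centred covariates (age, sex, mean FD,
education, gray-matter volume by default; GMV is a per-subject scalar in
the clinical table since segmentation is out of scope). The group t-map
is thresholded at voxel p < 0.001 — one tail per sign of the contrast,
the signed-contrast convention in neuroimaging; a two-tailed option
(p/2 per tail) exists. Suprathreshold voxels are grouped at
26-connectivity by default (6/18/26 configurable), positive and negative
clusters kept separately.

Two cluster-correction routes:

- **Permutation (reference).** Freedman–Lane: maps are residualised
  against the nuisance columns, subject order is permuted, the full model
  is refit, and the null is the maximum cluster extent over both signs.
  p = (1 + #{null >= k})/(n_perm + 1), valid by construction. Default 500
  permutations; fewer than 100 warns, zero is an error.
- **GRF (analytic).** Residual smoothness is estimated from
  variance-normalised residual maps: the variance of spatial first
  differences along each axis gives the roughness, FWHM_i =
  sqrt(4 ln 2 / lambda_i), and the RESEL count V/prod(FWHM). Cluster p
  uses the Euler-characteristic expected cluster count at the z-scale
  threshold and the exp(-beta k^(2/3)) cluster-size tail. The exact GRF
  variant used by common toolboxes is not published in detail, so this
  route documents its formulae and defers exactness claims to the
  permutation method; the two agree on simulations at desk scale.

## Synthetic cohorts

Every voxel's series is a weighted copy of one band-limited (0.01–0.08 Hz)
unit-SD source plus white noise: `y = w g(t) + sigma eps`, with sigma = 1.
Within a neighbourhood the pairwise correlation is w^2/(w^2+sigma^2), so
expected ReHo is monotone in the synchronisation weight w — this
shared-source construction is O(voxels) and gives direct control of the
concordance without building covariance matrices. Recoverable nuisance
structure (linear drift, WM/CSF confound series with random voxel
loadings) and bounded-random-walk motion traces (a `spiky` flag produces
subjects that violate the exclusion thresholds) complete each subject.

Defaults define the desk-scale study conditions: 20 patients + 20
controls, 24 x 24 x 16 grid of 3 mm voxels, TR 2 s, 240 volumes, baseline
sync 0.5; a full-size run (102 + 73) is a configuration change. Patient
effect regions are axis-aligned boxes (default 7 x 7 x 5 voxels): `reho_up`
/ `reho_down` add/subtract a sync offset (default 0.2), and `dreho_up`
modulates the weight in time, `w(t) = w (1 + m sin(2 pi t/P + phi))`,
with depth m (default 1.0) and period P. Between-subject heterogeneity:
a global sync jitter (SD 0.015) and per-region jitter (SD 0.03).

The nonstationarity period defaults to 200 s. A period shorter than the
100 s analysis window is largely averaged away *within* windows (the
window mean of the modulation scales with |sinc(pi T_w / P)|: ~0.18 at
P = 80 s versus ~0.64 at P = 200 s), leaving too little window-to-window
variability for the modulated region to separate reliably from
background; at 200 s the in-region minus out-of-region CV difference is
about 3.4 SD above zero across subjects. The amplitude-modulation
sidebands sit at the source frequencies ±1/P and remain inside the
passband, so preprocessing does not remove the effect.

Clinical covariates are sampled per group with the demographic marginals
of the emulated cohort (age ≈ 39 ± 12 y; education ≈ 12.7 ± 3 y; duration
9.03 ± 4.27 days and THI 47.54 ± 26.37 points for patients, THI clipped
to [0, 100]; PTA 73.66 ± 10.38 vs 13.25 ± 5.08 dB HL; affected side
~55% left). Affected side is a pure covariate — no side-specific imaging
effect is simulated, since no usable laterality structure is available to
emulate. Gray-matter volume is an invented covariate (~610 ± 55 ml).
A clinical link (ROI, covariate, rho) draws one latent standard-normal
factor per patient and feeds it into both the covariate
(`mu + sd (rho z + sqrt(1-rho^2) e)`) and the patient's ROI sync offset
(scale 0.12), inducing the target ROI–covariate correlation; the defaults
link the `reho_down` box to THI at +0.39 and the `dreho_up` box to
duration at −0.35. `clinical_effects` accepts a list so one cohort can
carry several links.

What the generator does **not** emulate: scanner physics, spatial
autocorrelation of the noise (voxel noise is white; smoothness enters only
through the applied kernel), anatomy, physiological noise spectra, or
laterality effects. Passing tests therefore demonstrate correctness of
the *computations* under a controlled signal model, not robustness to
every property of real data.

## Calibration and recovery studies

- **Familywise error.** The permutation route is calibrated on 200 null
  cohorts of 12+12 subjects on the 24 x 24 x 16 grid with 500 permutations
  each. The null input is a stack of smoothed Gaussian random fields
  (FWHM 2 voxels, variance-normalised) — the exact null of the map-level
  inference stage, which consumes per-subject maps; this keeps the
  calibration a pure test of the inference machinery. The observed rate
  of cohorts with any cluster p < 0.01 must lie in the binomial 95% band.
- **Effect recovery.** One cohort with only a `reho_down` region
  (magnitude 0.2) and one with only a `dreho_up` region (depth 1.0),
  20+20 subjects each, full pipeline, permutation inference; the
  significant-cluster mask of the expected sign must overlap the true
  region with Dice >= 0.5. Separate cohorts avoid the CV-mean coupling
  described above.
- **Correlation recovery.** 102 patients, full static pipeline, ROI means
  over the truth boxes; recovered Pearson r for the +0.39 (THI) and
  −0.35 (duration) links must fall in the Fisher 95% CI of the target at
  n = 102. Attenuation through the pipeline is small (the measured ROI
  mean tracks the latent sync almost deterministically at T = 230).

Problem sizes (grid, subject counts, permutation counts, repetition
counts) are the package's desk-scale study conditions; all are plain
configuration.

## Clinical layer

ROI values are arithmetic means over cluster masks. Pearson correlations
report the t-transform two-sided p with n−2 df; multiplicity control
beyond ROI preselection is off by default (a Bonferroni option exists).
Binary logistic regression is maximum likelihood with intercept; under
perfect separation the unpenalised MLE diverges, so the fit falls back to
a ridge-penalised solution with a logged warning. AUC is computed by the
exact Mann–Whitney pairwise formulation (ties count 1/2) and equals the
ROC curve integral. The classifier comparison (RBF SVM with C = 1,
decision tree, 100-tree random forest, 5-NN, logistic regression — fixed
documented defaults, no tuning loops) uses stratified 5-fold
cross-validation with pooled fold scores by default; an in-sample mode
mirrors single-cohort reports that do not hold data out, and every output
names the evaluation mode. Whether published single-cohort AUCs are
in-sample or held-out is usually unstated; CV is the honest default here.

## Known limitations

- GRF p-values are approximate at desk-scale smoothness and grid sizes;
  use the permutation route when exactness matters.
- The smoothness estimator uses finite differences, biasing FWHM slightly
  upward for nearly-unsmoothed fields (~1.18 voxels for white noise).
- The CV/mean coupling makes dynamic contrasts sensitive to static
  differences; the package reports both metrics so the coupling is
  visible, but does not attempt to decouple them.
- The generator's noise is spatially white; real BOLD noise is not, and
  cluster-extent nulls on real data differ accordingly.
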