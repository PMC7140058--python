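# Methods

This package re-implements, end to end and on fully synthetic data, a
free-water-elimination DTI analysis of peritumoral edema: the question is
whether suppressing the isotropic free-water signal in diffusion MRI
reveals tissue anisotropy differences between edema that later harbours
tumor recurrence and edema that stays recurrence-free. Because no patient
data are available to this package, every stage runs against a simulated
glioblastoma cohort with known ground truth; what the tests establish is
therefore the *internal* correctness and the qualitative behaviour of the
method under controlled conditions, not its clinical performance.

## Signal model

Each voxel's diffusion-weighted magnitude signal follows the
two-compartment ("bitensor") model

    S_k = S0 [ f exp(-b_k g_k' D g_k) + (1 - f) exp(-b_k d_free) ]

with tissue tensor `D` (3x3 symmetric PSD, mm^2/s), tissue-volume
fraction `f in [0,1]`, and the free-water diffusivity fixed at
`d_free = 3.0e-3 mm^2/s` (literature value for unrestricted water at body
temperature; configurable). The default acquisition matches a clinical
single-shell DTI protocol: 32 quasi-uniform directions at b = 800 s/mm^2,
one b = 0 volume, 2 mm isotropic voxels. Directions come from a Fibonacci
sphere lattice under a seeded random rotation, so gradient tables are
reproducible and quasi-uniform for any direction count. Magnitude noise is
Rician: two independent Gaussian channels of sd `S0/SNR` are added in
quadrature. The background noise level is recovered from signal-free
voxels via the Rayleigh mean (`sigma = mean/sqrt(pi/2)`).

## The phantom

Geometry is deliberately schematic — concentric spheres, not anatomy —
because the acceptance surface is statistical recovery, not image realism:
a tumor core (radius 5 voxels), an edema shell (radius 12) split
azimuthally into a recurrence-destined sector and a recurrence-free
remainder (half each by default), all embedded in a white-matter sphere
(radius 18) inside a 40^3 volume.

Tissue classes differ in eigenvalue structure and free-water load
(eigenvalues in 1e-3 mm^2/s):

| class            | eigenvalues        | FA    | f (center, clip range)  |
|------------------|--------------------|-------|-------------------------|
| white matter     | 1.7, 0.3, 0.3      | ~0.75 | 0.93, [0.85, 1.0]       |
| enhancing tumor  | 1.0, 0.7, 0.7      | ~0.21 | 0.68, [0.5, 0.8]        |
| edema, pure      | 1.4, 0.45, 0.45    | ~0.62 | 0.50, [0.3, 0.7]        |
| edema, recurrence| above with deficit | ~0.44 | 0.50, [0.3, 0.7]        |

The recurrence deficit subtracts `effect_size` (default 0.22e-3) from the
axial eigenvalue and adds half of it to each radial one, so mean
diffusivity is preserved and only anisotropy drops — the signature the
method is meant to uncover. Per-voxel eigenvalue jitter (sd 0.03e-3) and
Haar-random orientations decorrelate neighbouring voxels.

Two design points matter and were calibrated deliberately:

1. **The free-water load is a smooth random field, not voxelwise noise.**
   Edema wetness `f` is `center + 0.40 * G(x)` clipped to [0.3, 0.7],
   where `G` is unit-variance Gaussian-filtered white noise with a 4-voxel
   correlation length. Spatially white `f` would average out over any
   patch and free water would mask nothing at the analysis scale; regional
   wetness gradients are also what real vasogenic edema shows.
2. **Patient-level random effects.** Each simulated patient draws an
   independent wetness-field realization (so sector-level wetness
   differences are exchangeable across patients rather than a systematic
   cohort-wide offset — the estimated tissue fractions must NOT separate
   the two edema classes), plus an MD-preserving shift of the edema
   anisotropy (sd 0.06e-3, applied to both edema classes alike) and a
   wetness-center shift (sd 0.06). The
   first makes the random-intercept logistic model identifiable; both put
   cross-validated AUCs into the non-saturated regime where comparing
   correlated ROC curves is meaningful. These magnitudes were fixed once,
   using calibration seeds disjoint from every seed the tests and the
   acceptance script use, and not revisited.

What the phantom does *not* emulate: anatomy, fiber crossings, spatially
correlated tensor orientations, T2/eddy/motion effects, partial-volume
mixing at class boundaries, or scanner-specific noise correlations.
Passing tests therefore demonstrate method correctness under the stated
model, and the qualitative free-water-masking mechanism — not clinical
effect sizes.

## ANN free-water elimination

A fully connected network maps the b0-normalized diffusion-weighted
signal vector to the tissue fraction f. The architecture is tied to the
acquisition: N_b input units (one per weighted measurement; 32 here), two
hidden ReLU layers of N_b/2 and N_b/4 units (integer division), and one
output unit with a hard-sigmoid nonlinearity, so estimates are bounded to
[0, 1] by construction. Training: Adam on an MSE loss, batch 128, initial
learning rate 1e-3 decayed by 0.3 on 10-epoch validation plateaus,
early stopping (patience 40, best-validation weights kept), 10%
validation split, 5e4 synthetic training voxels. Training runs in well
under a minute on one CPU core.

The training distribution is the decisive design choice. The single-shell
inverse problem is ill posed in general: an isotropic tissue tensor whose
diffusivity approaches `d_free` is indistinguishable from free water, and
under a broad eigenvalue prior (0.1e-3 to 2.2e-3 uniform) no estimator —
regardless of capacity — can beat a mean absolute error of about 0.1 in
f. The network is therefore trained on tensors whose mean diffusivity is
drawn uniformly from the parenchymal band 0.7e-3 to 0.8e-3 mm^2/s (white
matter ~0.7, cortical gray matter ~0.8), with free eigenvalue *shape*
(three raw values in [0.2, 1.0] rescaled to the target MD) and Haar
orientations. Within this physiologically tight band the inverse map is
well posed, and the network reaches held-out MAE ~0.012 noiseless and
~0.025 at SNR 30 (recomputed by the test suite and acceptance script).
SNR during training is log-uniform on [20, 2000] with a 25% noiseless
fraction. Estimators are serialized with a fingerprint of their gradient
table and refuse to run on a different scheme.

Correction inverts the mixture algebraically per measurement:

    A_tissue,k = (S_k/S0 - (1 - f) exp(-b_k d_free)) / f

clipped to (1e-6, 1]. The division amplifies noise by 1/f, so voxels with
f below a floor (default 0.1) are excluded with a reason code rather than
corrected into noise, as are voxels where more than half the corrected
entries would be negative (free water dominates; the remainder is noise).
Exclusions propagate as missing values downstream.

## Tensor fitting and maps

Tensors are fit to log-attenuations by weighted least squares (weights =
squared attenuations, the first-order variance weighting; attenuations
floored at 1e-6 before the log). The robust variant follows the RESTORE
idea on the log-linear system: Geman-McClure IRLS, then exclusion of
measurements with |residual| > 3 sigma_hat, then an ordinary fit on the
retained set, falling back (flagged) to the non-robust fit if fewer than
six directions would remain. The robust scale is estimated **once**, from
the initial WLS residuals, as `1.4826 * median|r| * sqrt(k/(k-6))` (the
dof factor compensates the fit's absorption of six parameters) and held
fixed; re-estimating it from robust-fit residuals each iteration shrinks
the scale toward a consensus subset and falsely excludes ~4 clean
measurements per voxel at SNR 30. Convergence: max component change
< 1e-10 mm^2/s or 50 iterations.

Two practical notes from this implementation:

- Signal-weighted WLS is already quite robust to signal *drops* (a halved
  measurement also has a quartered weight); robust exclusion earns its
  keep against full-weight artifacts such as signal spikes, and against
  dropout when few directions exist.
- FA computed from noisy fitted eigenvalues is biased upward (eigenvalue
  repulsion), and free-water correction amplifies exactly this noise by
  1/f. When a noise level is available, FA maps are therefore computed
  from the fitted tensor invariants with a parameter-free moment
  correction: the squared-norm and squared-trace invariants are debiased
  by their expected noise contributions, obtained from the sandwich
  covariance of the weighted LS estimator under the known per-voxel
  attenuation noise (background sigma, divided by S0, divided by f on the
  corrected route). Without this correction, corrected FA in low-FA edema
  carries a ~+0.04 bias and the voxelwise "corrected is closer to truth"
  property cannot reach its target. MD uses the eigenvalue mean directly
  (the trace is unbiased).

FA is the normalized eigenvalue dispersion
`sqrt(1/2) sqrt(sum (li - lj)^2) / sqrt(sum li^2)` in [0, 1] (defined as 0
with a flag for an all-zero tensor); MD is the eigenvalue mean. Negative
eigenvalues are clamped to zero with a diagnostic count rather than
rejecting the voxel.

## ROI statistics

Per patient and region (enhancing tumor, pure edema, recurrence edema)
the 10th/50th/90th percentiles (linear interpolation) and mean of each
map are extracted, missing voxels dropped with counts. Edema-with-
recurrence vs pure edema is compared by the two-sided Wilcoxon rank-sum
test: exact enumeration when the pooled sample is <= 12 and tie-free,
otherwise the tie-corrected normal approximation with continuity
correction; identical pooled values yield p = 1 with a degeneracy flag.
The unit of analysis is the patient (per-patient summaries first, then
the two-sample test across patients) to avoid pseudo-replicating
correlated voxels. No multiple-testing correction is applied; the
comparison table reports raw p-values, with the tissue-fraction map
marked not-applicable on the uncorrected side (it only exists after
correction).

## Recurrence prediction

Per patient, four 3x3x3-voxel patches are sampled from each edema class,
disjoint, wholly inside their class region, with at least half a patch of
valid voxels; placement is uniform among admissible non-overlapping
configurations via seeded randomized backtracking. (A 3x3x3 *mm* patch is
not realizable on a 2 mm grid; the 3-voxel = 6 mm window is the default,
exposed in config.) The patch predictor is the mean FA over valid voxels,
once from the corrected and once from the uncorrected map.

The classifier is a random-intercept logistic model,
`logit P(recur) = x'beta + u_patient`, `u ~ N(0, sigma_u^2)`, fit by
marginal maximum likelihood with adaptive Gauss-Hermite quadrature (15
nodes; per-patient mode and curvature found by Newton). Predictors are
standardized internally and coefficients transformed back (FA-scale
covariates otherwise push |beta| to ~30 and destroy the conditioning of
the finite-difference gradients). sigma is optimized directly on [0, 5] —
zero (the plain-logistic boundary) is attainable, and the quadrature is
accurate throughout that range; larger fitted sigmas only arise when
per-patient intercepts absorb a separable outcome. Quasi-separation is
flagged (runaway standardized coefficients, a perfectly classifying
fixed-effect score, or near-zero marginal deviance) and the coefficients
reported with that warning; a genuine optimizer failure (no improvement
over the start) raises. Wald standard errors come from the numerical
Hessian of the marginal likelihood. The implementation was validated
against `lme4::glmer` (nAGQ = 15): fixed effects and sigma_u^2 agree to
~1e-5 on a 150-patient simulation, and that cross-check runs in the test
suite.

Cross-validation is grouped by patient (a patient's patches never span
folds; three folds by default, seeded partition; single-class folds are
reshuffled once, then refused). Held-out patients are scored with fixed
effects only — the population-level prediction for an unseen patient.
AUC is the Mann-Whitney statistic (ties half-weight); correlated AUCs are
compared with DeLong's structural-components estimator and a two-sided
normal test. A model compared with itself returns p = 1; a zero variance
of the difference with unequal AUCs is flagged degenerate.

## Pipeline and reproducibility

The `fwrecur` CLI exposes the stages simulate / train / correct / metrics
/ roistats / predict / all behind one YAML config. Every stochastic step
derives its stream from the single config seed through named
`SeedSequence` spawns; volumes are written as *uncompressed* NIfTI-1
(gzip embeds timestamps and would break byte-identical reruns), and a
manifest records SHA-256 checksums of every stage output, verified before
any downstream stage runs.

## Problem sizes in the checks

The acceptance-style checks use: 1000 random PSD tensors for the exact
WLS round trip; 5e4 training / 5e3 held-out voxels for fraction recovery;
one 40^3 phantom (~6600 edema voxels) at SNR 30 for FA recovery; 500
null replicates for rank-sum calibration (drawn at the per-patient
summary level, where the test operates); 20 replicates of 200-patient
simulations for mixed-model recovery; and 20 replicate cohorts of 8
patients for the cross-validated AUC ordering. Cohort sizes are the
package's own choice of a desk-scale problem; the qualitative conclusions
(ordering of AUCs, which coefficient is significant) are the object of
the checks, not any clinical effect size.

## Known limitations

- The fraction estimator is scheme-specific by design (input size = N_b);
  a new gradient table means retraining. No multi-shell support.
- The well-posedness of the inversion rests on the parenchymal-MD
  training prior; in tissue whose MD genuinely approaches free water
  (necrosis, cysts) the estimator's prior is wrong by construction.
- The noise-moment FA correction assumes the background-derived sigma
  applies brain-wide (no parallel-imaging spatial noise maps).
- Mixed-model Wald inference is unreliable under quasi-separation (it is
  flagged, not repaired); small cohorts with strong predictors hit this
  regime routinely.
- The phantom's recurrence sector is geometrically contiguous and its
  class variances are homogeneous; none of the segmentation,
  registration, or selection-bias issues of the clinical workflow are
  modelled.
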