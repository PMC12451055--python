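# Methods

## Overview

`glymmark` implements two MRI proxies of brain glymphatic (perivascular
fluid-exchange) function and the statistical layer used to relate them
to clinical status in a three-group Parkinson's disease design (PD with
anxiety, PD without anxiety, healthy controls):

1. the **DTI-ALPS index**, a ratio of water diffusivities measured
   along versus perpendicular to the perivascular axis in template
   space, and
2. **gBOLD-CSF coupling strength**, the magnitude of the lagged
   cross-correlation between the global gray-matter BOLD signal and the
   CSF inflow signal at the bottom of the imaging volume.

Because no subject-level data are deposited for studies of this design,
every stage is validated against synthetic generators with closed-form
ground truth, and the statistical layer is additionally validated
against printed cohort summary tables, which it can consume directly.

## DTI-ALPS

### Tensor model and fit

The diffusion-weighted signal is modeled as mono-exponential,
`S = S0 * exp(-b g^T D g)`, with `D` the symmetric 3x3 diffusion tensor.
The fit is ordinary (unweighted) log-linear least squares of
`ln S` on the seven-parameter design `[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz,
Dyz]`, the default behavior of the standard FSL fitting tool. It
requires at least one `b ~ 0` volume and six distinct non-collinear
directions. Voxels containing any non-positive signal are excluded
(NaN) and counted in the QC record rather than clamped: clamping would
bias the log-domain fit. FA is computed from the tensor eigenvalues.

At signal SNR around 20 the unweighted log-linear estimator carries a
small noise-rescaling bias; on the phantom study below its net effect
on the ALPS ratio is a few tenths of a percent, an order of magnitude
inside the 2% recovery band used by the tests.

### ROI placement

The four published ROI centers — left/right superior corona radiata
(projection fibers) and left/right superior longitudinal fasciculus
(association fibers) — are interpreted as 0-based voxel indices on the
1 mm JHU-ICBM-FA template grid (182 x 218 x 182): L-SCR (116, 110, 99),
R-SCR (64, 110, 99), L-SLF (128, 110, 99), R-SLF (51, 110, 99). The
printed left/right pairs are not exactly mirror-symmetric; they are
used as printed rather than "corrected". On coarser grids the centers
are rescaled and floored. Spheres have 5 mm diameter, with membership
by voxel-center Euclidean distance <= radius (inclusive) — a
deterministic, resolution-independent rule giving 81 voxels at 1 mm and
7 voxels at 2 mm; a zero diameter degenerates to the center voxel, and
a sphere clipped by the grid boundary is truncated with a warning.

### Index

Per hemisphere,

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where each term is the mean of the corresponding diffusivity map over
one ROI sphere. The headline "mean" index averages the left and right
ratios (per-hemisphere ratios first, average second). The index is
dimensionless; published tables sometimes attach a diffusivity unit
label to it, which is treated as a typographic artifact. Spatial
normalization to the template is upstream preprocessing and out of
scope: inputs must already be in template space.

## gBOLD-CSF coupling

### Signal extraction and preprocessing

The gBOLD signal is the mean preprocessed BOLD series over a
gray-matter mask, the CSF signal the mean over a bottom-slice CSF mask
covering the foramen magnum; both masks are inputs. Preprocessing per
signal: drop the first 10 volumes, remove the least-squares linear
trend, band-pass 0.01-0.1 Hz, standardize. The band-pass is a
forward-backward (zero-phase) Butterworth filter of order 4 per pass —
zero phase is essential because the downstream statistic is a lag. An
almost-constant series standardizes to zeros rather than dividing by a
vanishing variance.

### Lagged coupling

`r(tau)` is the Pearson correlation of gBOLD(t + tau) with CSF(t) over
the truncated overlapping window (no zero padding), for integer lags
-5..+5 TR; negative tau means gBOLD leads. With TR = 1.5 s and CSF
inflow following global BOLD fluctuations, the extreme sits at
tau = -3. Coupling strength is |r(-3)|; the signed value is kept in a
separate field because published group means are reported positive
while the raw correlation at -3 TR is canonically negative — both are
emitted and neither is guessed away. The lag/sign convention is pinned
by a construction test: a CSF series built as an inverted copy of gBOLD
delayed by 3 samples must give exactly r(-3) = -1.

The construction is cross-validated by the derivative check: the
negative temporal derivative of gBOLD (central differences, one-sided
ends) couples maximally and positively with CSF at lag 0.

### Permutation null

Significance uses a mismatched-pairing null: each of 10,000 draws pairs
a random subject's gBOLD with a different random subject's CSF (sampled
with replacement across draws, cohort-wide) and records |r| at the
quantification lag; per-subject p is the add-one-corrected exceedance
fraction. Under the null (zero-amplitude generator cohorts) the
p-values are uniform, which the calibration test checks by KS at 500
subjects.

## Synthetic generators

* **DWI phantom** — axis-aligned diagonal tensors in boxes around the
  four ROI centers, isotropic background (0.7e-3 mm^2/s), b = 1000
  s/mm^2, 64 quasi-uniform (Fibonacci-sphere) directions plus one b0,
  S0 = 1000. Default region tensors: SCR (0.55, 0.40, 1.60)e-3 mm^2/s
  (fibers inferior-superior), SLF (0.50, 1.60, 0.40)e-3 (fibers
  anterior-posterior); the implied true ALPS index is
  mean(0.55, 0.50)/mean(0.40, 0.40) = 1.3125, within the printed
  healthy-control range (~1.34). Noise is additive Gaussian by default
  with an optional Rician (two-quadrature-channel) flag; noise-free
  signal follows the tensor model exactly, which the tests assert to
  the last bit. The default grid is the half-resolution template
  (91 x 109 x 91 at 2 mm).
* **Coupled series** — 300 time points at TR 1.5 s. A latent smoothed
  (6 s FWHM) unit-variance Gaussian process drives gBOLD; CSF is
  `sign * amplitude` times the latent process delayed by `lag` samples
  (default 3), completed to unit variance with independent smoothed
  noise; both observed series receive white measurement noise of SD
  `noise_sd`. Expected |r| at the coupling lag is
  `amplitude / (1 + noise_sd^2)`, used as the analytic attenuation
  target in tests. This is deliberately the minimal delay-and-scale
  model reproducing the observed lagged anti-correlation; no
  hemodynamic model is implied.
* **Cohorts** — per-group Gaussian draws with the printed means/SDs
  (both bundled tables available as defaults); sex is Bernoulli with
  the printed male fraction. Within the two PD groups, HAMA and the
  markers share a latent Gaussian block with target correlations
  (defaults: marker-HAMA -0.28 for ALPS and -0.317 for coupling,
  left-right ALPS 0.7, ALPS-coupling 0.35); a non-positive-definite
  request is rejected. `alps_mean` is derived as the hemispheric
  average, preserving the pipeline identity. Group labels can
  optionally be re-assigned by the HAMA >= 14 rule after drawing.
  The printed between-subject SDs are used as total variance; the
  studies report no within-subject variance to separate out.

  Because group means of both HAMA and the markers differ between PD
  groups, the pooled PD correlation exceeds the within-group target;
  recovery checks therefore estimate the partial correlation with the
  group indicator among the covariates, which returns the within-group
  target.

What the generators do **not** emulate: scanner artifacts (motion,
eddy currents, distortion, Gibbs ringing), spatial autocorrelation and
anatomy beyond the ROI boxes, non-Gaussian clinical-score marginals
(scores can stray outside their nominal ranges), and hemodynamic
response shape. Passing tests therefore demonstrate correctness of the
estimators under the stated models, not robustness to real-world
artifacts — those are handled by the out-of-scope preprocessing chain.

## Cohort statistics

All location tests are computable from group summaries (n, mean, sd) as
well as raw data, and the two routes agree to 1e-10 when the summaries
derive from the raw data. The two-sample t-test is gated by a
two-sided F-ratio variance test at alpha = 0.05 (pooled when equality
is not rejected, Welch otherwise); a Levene-type gate would need raw
data, and the F-ratio gate reproduces the published pooled/Welch mix
(Welch for disease duration, pooled for H&Y, UPDRS-III, LEDD).
One-way ANOVA is computed from the summary decomposition
SS_between/SS_within; chi-square is Pearson's without continuity
correction; Kruskal-Wallis (raw data only) uses the tie-corrected H
with chi-square reference. Bonferroni correction is `min(1, m p)`;
post-hoc pairs after ANOVA use pooled-variance pairwise t-tests with
m = number of pairs (the published analysis does not name its post-hoc
procedure). Partial correlation residualizes both variables on
[1, covariates] and correlates the residuals, p from t with
df = n - 2 - k; sex enters as a 0/1 covariate.

Printed-table reproduction: every recomputable statistic matches its
printed value within 1% relative tolerance, except that (a) a printed
statistic close to zero (LEDD t = -0.005) is matched to the half-unit
of its printed last decimal, and (b) for marker rows whose summaries
are printed with only 3 decimals at small group separations (ALPS F
values), the test checks the printed statistic is attainable from some
summaries that round to the printed ones (half-ulp perturbation box).
Printed Kruskal-Wallis H values are not asserted anywhere: they are
not recomputable from summaries and the printed values are not
consistent with the chi-square(2) reference.

## Diagnostic models

AUC uses the Mann-Whitney identity with ties counted 1/2, verified
against an exhaustive pair-count oracle. Operating points maximize
Youden's J with ties resolved toward higher specificity (the published
report does not name its criterion; the convention is explicit and
configurable by scanning the returned curve). DeLong variance and
covariance use the placement-value estimator; 95% CIs are normal
approximations clipped to [0, 1], and curve comparison is a two-sided
z-test. The multivariate combiner is maximum-likelihood logistic
regression on standardized predictors (the publication does not name
its combiner; logistic is the standard two-class clinical choice and is
recorded in the output); under perfect separation it falls back to an
L2-penalized fit with a warning. The positive class is PD-A
throughout, and marker direction (lower ALPS/coupling = positive) is
fixed per marker, never refit per dataset. Published AUCs from the
undeposited 52-subject cohort are demonstration references; the
package's guarantee is the ordering property on generator cohorts
(combined model >= best single marker in >= 90% of seeds, in sample).

## Numerical and scaling choices

* All randomness flows through one `numpy` Generator per call, seeded
  from the spec; identical seeds give bit-identical outputs.
* The noise-free phantom exactness check runs on the 91 x 109 x 91
  half-resolution grid; the 100-phantom noisy recovery study runs on a
  compact 30 x 14 x 14 grid (2 mm) holding the four ROI regions with
  identical tensors, ROI geometry and SNR — the ALPS index depends only
  on ROI voxels and voxel noise is i.i.d., so the compact study is
  statistically identical and keeps the suite fast.
* Tensor fitting accepts an optional mask (e.g. the ROI union) so that
  index computation does not pay for a whole-brain eigendecomposition.
* Generator convergence checks use a per-cell SE bound at family-wise
  alpha = 0.05 (Bonferroni over the checked cells) rather than a raw
  2-SE rule, so the test's false-alarm rate is calibrated across the
  ~14 cells it inspects.

## Known limitations

* Only diagonal ground-truth tensors are generated (the fit itself
  estimates all six elements); oblique fiber orientations are not
  exercised.
* The coupling generator's measurement noise is white; colored
  physiological noise would attenuate the band-passed statistic
  differently.
* Summary-based tests cannot reproduce rank-based statistics; raw-data
  entry points are provided instead.
* The sign convention discrepancy between published positive coupling
  means and the canonically negative r(-3) is surfaced, not resolved:
  both the signed correlation and its magnitude are reported.
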