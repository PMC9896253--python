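# Methods

This note records the models, the defaults and the reasoning behind the
design choices, in the package's own terms.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Head phantom

The phantom is geometric, not anatomical.  The intracranial space is an
ellipsoid (default semi-axes 70 × 80 × 65 mm, ≈1.5 L) containing, from the
surface inward:

* a cortical **gray-matter ribbon** (10 mm),
* a **sulcal CSF rim** directly beneath it, whose thickness is
  `atrophy × rim_max_mm` (default maximum 6 mm),
* a **white-matter core**, and
* two ellipsoidal **ventricle-like CSF cavities** whose semi-axes scale
  linearly with `atrophy` (maximum 18 × 30 × 14 mm each).

Everything outside the head is background at −1000 HU.  A single `atrophy`
knob in [0, 1] therefore maps monotonically to the true CSF/ICV ratio
(0% at 0, ≈26% at 1 on the default grid); `phantom.atrophy_for_ratio`
inverts the map by bisection.  Placing the sulcal CSF *inside* the
gray-matter ribbon mirrors real anatomy (sulci fold into cortex; CSF does
not border air) and keeps the CSF compartment away from the huge
tissue/air intensity step at the head surface.

Anatomy is rasterised at 3× subvoxel resolution, averaged to per-voxel
class fractions, and smoothed with a Gaussian of `pve_blur_sigma` = 1 mm —
the partial-volume effect of a thin-slice CT reconstruction.  Fractions sum
to one per voxel by construction.  True volumes are exact sums over
fractions; they are the oracle every volumetry test compares against.

**Rendering.**  Voxel HU = fraction-weighted mix of the class HU means
(defaults CSF 5, GM 40, WM 30; background −1000) plus i.i.d. Gaussian noise
of SD `noise_sd` (default 5 HU, seeded).  The per-tissue `hu_sds` fields
(4/5/5 HU) describe the nominal within-tissue spread of real CT and are
used by the mixture-fit initialisation; rendering itself injects only the
global scanner noise, so a noiseless pure-tissue voxel equals its class
mean exactly.

**Atlas.**  The probabilistic atlas is the tissue-fraction map smoothed by
`blur_sigma` (default 1.25 mm on top of the 1 mm PVE) and optionally pushed
through a known 4×4 world-space affine (`misalignment`), recorded so
registration recovery can be verified.  The blur emulates the softness of a
population template.  Accuracy of the ratio degrades gracefully as the
atlas gets softer: at 3 mm blur the boundary leak described in §2 grows to
roughly +0.5…+1.5 pp.  The intracranial mask is `Σ_t p_t ≥ 0.5`; the paper
trail for the method never defines the ICV boundary operationally, so the
50% level set is our choice.

## 2. Volumetry

Stages of `measure_csf_icv`:

1. **Registration** (`register_atlas`).  `identity` (default for phantoms
   generated aligned) only verifies the grids agree.  `affine` registers
   the atlas-predicted HU image (probability-weighted class means,
   background −1000) to the CT with SimpleITK: correlation metric,
   regular-step gradient descent, shrink factors 4/2/1.  Nonlinear
   registration is out of scope.

2. **Histograms** (`build_histograms`).  Every masked voxel adds its volume
   to the three tissue histograms, split by the atlas probabilities; bins
   are 1 HU wide over [−100, 80] HU, out-of-range values accumulate in the
   end bins, so the histogram total equals the masked probabilistic volume
   exactly.  The floor sits far below water so that air-contaminated
   boundary voxels land well away from any tissue component.

3. **Mixture fit** (`fit_mixtures`).  Stage 1: per-tissue weighted moment
   fits give initial (area, mean, SD).  Stage 2: all components are refitted
   jointly by bounded least squares on bin volumes.  The residual stacks
   each tissue's own atlas-attributed histogram with a pooled-histogram
   coupling term (weight 0.3).  The coupling keeps the total fitted area
   tied to the pooled intracranial histogram; the per-tissue terms keep the
   atlas prior in the fit, which is what "atlas-guided" means here.  At
   desk-scale voxel sizes (2–3 mm) most sulcal CSF is partial volume, and a
   fit to the pooled histogram alone cannot decide which tissue owns the
   partial-volume continuum between the peaks — with attribution it can.
   Defaults: 2 CSF / 3 GM / 2 WM components (extra components absorb the
   partial-volume bridges; counts are configurable), mean bounds
   CSF (−10, 25), WM (10, 35), GM (−10, 60) HU, SDs in (0.1, 30) HU,
   tolerances 1e-8, at most 2000 residual evaluations.  The SD floor of
   0.1 HU matters only for noiseless data, where spike-like histograms
   occupy single bins; a wider floor would force area inflation.  The
   ordering CSF < WM < GM is checked on the area-weighted tissue means at
   the optimum and violations raise an error.

4. **Volumes** (`compute_volumes`).  Tissue volume = summed component
   areas; ICV = their sum; ratio = 100 × CSF/ICV.

**Known bias.**  Voxels mixing tissue with air sit at HU far below any
component and their tissue weight cannot be recovered from the histogram;
the ICV is therefore slightly underestimated and the ratio slightly
overestimated.  With the default atlas blur this amounts to ≲0.9 pp across
atrophy 0.2–0.8 at 64³/3 mm (the test suite measures it), rising toward
+1.5 pp at extreme atrophy.  Real scanners see the same effect at the
brain–skull interface.

**What the phantoms do not show.**  No skull, beam hardening, motion or
infarct lesions; HU distributions are exactly Gaussian, so the mixture
model is well-specified by construction.  Passing the phantom suite shows
the estimator recovers volumes when its model assumptions hold, and that it
is robust to noise and coarse priors — not that it handles real-world
artifacts.

## 3. Cohort generator

Covariate marginals (configurable; chosen as typical for an EVT registry):
age ~ N(68, 14²) years; NIHSS ~ round N(16, 6²) clipped to 0–42; ASPECTS ~
round N(8.2, 1.8²) clipped to 0–10; ICA occlusion Bernoulli(0.27);
collateral grade 0–3 with probabilities (.06, .33, .38, .23); onset-to-groin
~ N(210, 65²) min clipped to 60–390; eTICI grades with ≈60% reaching 2B50
after the one-plane cap (3% of DSAs single-plane); CSF/ICV ~ N(13.72,
5.75²) %, correlated 0.3 with age (older brains hold more CSF; the
magnitude is unreported anywhere, so it is a configurable choice).

The outcome is Bernoulli on the logistic linear predictor over the coded
covariates.  Default coefficients are the natural logs of the published
odds ratios (extended model: 1.1, 1.1, 1.1, 1.9, 2.8, 1.3, 1.9, 1.2; basic
model: 1.5, 1.1, 1.2, 2.2, 2.5, 1.3, 1.6); the intercept is solved
numerically (Brent on a fixed 200k-draw Monte-Carlo sample) for a marginal
prevalence of 40/683.  The CSF/ICV location/scale above was calibrated once,
by simulation, so that the two outcome groups average ≈9% and ≈14% — the
selection effect of the outcome model produces the group separation; it is
not imposed directly.  A fraction 18/701 of patients is relabelled "death
with unknown cause" independently of the covariates (no model for it
exists) and excluded before analysis, as in the source registry's flow.

Clinical fields (surgery ≤7 d, death ≤7 d, edema attribution, clinical
triad, midline shift, 90-day mRS) are drawn consistently with the assigned
category, so `classify_edema` reproduces the generated outcome exactly —
a round-trip the tests exercise.  Missingness is MCAR only (the mechanism
in the source data is unstated).

## 4. Statistics

* **Logistic fits**: IRLS with step-halving (the log-likelihood is
  monotone by construction), convergence at max coefficient change <1e-8,
  at most 100 iterations.  Complete separation raises an error naming the
  offending predictor.  An L2 (ridge) option exists and is off by default;
  the extended model's 40 events over 8 predictors are fitted unpenalised,
  matching the source analysis.  Wald CIs and p values; profile-likelihood
  intervals are not implemented.
* **Imputation**: simplified chained equations — linear regression with
  normal residual draws for continuous variables, IRLS-logistic with
  Bernoulli draws for binary ones, linear-then-round/clip for the ordinal
  scores — 10 cycles, m = 5 completions by default (the source's m is
  unreported).  The outcome is always a predictor in the imputation
  models.  Pooling follows Rubin's rules (mean coefficients; within +
  (1+1/m)·between covariance; per-coefficient degrees of freedom), with t
  reference distributions for pooled Wald tests.
* **Discrimination**: c-statistic as midrank Mann–Whitney concordance
  (ties ½), DeLong placement-value SE; ROC points from a full threshold
  sweep.  DeLong comparison of the two models uses the placement
  covariance; with multiply-imputed data the pipeline computes the test per
  completed dataset and reports the median p (how imputation interacted
  with the published DeLong test is unstated; this choice is deliberately
  conservative and is reported as such).
* **Goodness of fit**: likelihood-ratio test 2·ΔLL ~ χ²(Δk); equal
  predictor sets are the degenerate nesting (df 0, p 1).  Two-sided tests
  throughout; no α is hard-coded.

## 5. Pipeline and problem sizes

`run_study` chains: cohort simulation → (optional) per-patient phantom
volumetry → outcome classification and exclusion of unknown-cause deaths →
MCAR masking → chained-equation imputation → per-completion model fits →
pooled odds-ratio tables, VIF, c-statistics, DeLong (median p), LRT →
report bundle (JSON + CSV + ROC plot + log).  All randomness derives from
the single config seed; a rerun is bit-identical apart from timestamps.

Per-patient volumetry uses 64³ phantoms at 3 mm voxels by default so a
683-patient imaging run stays desk-scale (~2 s/patient); the grid is
configurable up to 128³.  The test suite and the acceptance script use
n = 10,000–20,000 cohorts for calibration/recovery checks, 1000 replicates
for the null-distribution checks, and 100 replicates for imputation
coverage — sizes chosen to keep Monte-Carlo error well below the tolerances
they assert.

## 6. Limitations

* The atlas is derived from the phantom itself; real population templates
  are biased relative to any individual anatomy in ways our misalignment
  tests only partially emulate.
* The boundary-voxel bias of §2 caps accuracy near +1–1.5 pp at extreme
  atrophy on coarse grids.
* Registration is affine only and tested down to translations of a few mm.
* The imputation model treats ordinal scores as rounded Gaussians.
* The registry c-statistics (≈0.86 vs ≈0.88) and the DeLong p between them
  depend on the unavailable patient-level data; the package checks the
  discrimination machinery by oracle equivalence and calibration instead of
  reproducing those two numbers.
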