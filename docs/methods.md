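# Methods

This note records the models, generator design, numerical conventions and
known limitations of `suvlean`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## SUV model

Body-weight SUV is `SUVbw = C / (D · DF / BW)` with C the ROI activity
concentration (kBq/mL), D the injected dose (MBq), BW body weight (kg) and
`DF = exp(−0.693 · t / T½)` the physical decay factor over the uptake time
t. The MBq→kBq and kg→g factors cancel, so SUV is dimensionless (g/mL). The
decay constant is the conventional clinical rounding 0.693 rather than
ln 2 ≈ 0.693147 — the difference at one half-life is 2.6 per 10⁴ and the
constant is overridable (`suv.DECAY_CONSTANT`, `constant=` arguments). The
F-18 half-life defaults to 109.77 min.

Lean normalization rescales SUVbw by a lean-to-total-mass ratio:

* `SUV_james = SUVbw · LBM_james / BW`, `SUV_janma = SUVbw · LBM_janma / BW`;
* `SUV_dixon = SUVbw · m_water / (m_water + m_fat + m_lung)` with
  compartment masses from calibrated MRAC volumetrics. The numerator is
  water only; whether lung tissue counts as "lean" is genuinely ambiguous,
  so `dixon_lean_fraction(..., lung_in_numerator=True)` exposes the
  water+lung variant (not used by default).

Two distinct Dixon quantities coexist and should not be conflated:

* the **SUV rescaling fraction** above, whose denominator is the
  *imaging-covered* mass (water+fat+lung); and
* the **Dixon lean mass** used in LBM agreement tables, taken as the
  calibrated water mass `ρ_w · V_w`, whose fraction-of-body-weight is
  commensurable with the DXA lean fraction (non-fat mass / body weight).

Using the rescaling fraction as a fraction-of-weight would bake the
off-coverage residual mass (~8% of BW) into an artificial +4-point bias.
With the water-mass reading the only structural offset against DXA is the
lung mass the water numerator excludes (~1 point of body weight).

## LBM formulas

James (height H in cm): men `1.10·BW − 128·(BW/H)²`, women
`1.07·BW − 148·(BW/H)²`. At fixed height this is concave in BW and peaks at
`BW* = a·H²/(2b)`, i.e. a height-independent critical BMI `10⁴·a/(2b)`:
42.97 for men, 36.15 for women. Beyond it the formula assigns heavier
patients *less* lean mass and eventually goes negative; `lbm_james` returns
such values unchanged with a `UserWarning` and the `LBMEstimate.flagged`
bit set, because silently clipping would hide exactly the failure mode the
comparison studies care about. Height must be in cm: with meters the
critical BMI would be off by 10⁴.

Janmahasatian: men `9270·BW/(6680 + 216·BMI)`, women
`9270·BW/(8780 + 244·BMI)`. The lean fraction depends on sex and BMI only
and decreases strictly and smoothly in BMI, with no critical point.

## Dixon volumetrics and density calibration

Four-class MRAC maps carry exactly the constants water 0.096, fat 0.08,
lung 0.032, air 0 cm⁻¹. `segment_mrac` assigns each voxel the nearest
constant; any voxel farther than the tolerance (default 0.004 cm⁻¹, and
required < 0.008, half the smallest inter-label gap of 0.016 between fat
and water) from every constant raises a `SegmentationError` naming the
value — corrupt maps fail loudly. Volumes are voxel count × voxel volume.

Calibration against DXA is zero-intercept least squares, in two modes:

* **simple** — two univariate fits through the origin (DXA fat mass on fat
  volume; DXA non-fat mass on water volume). Slopes are kg/L; r² is the
  uncentered coefficient of determination (the centered one is meaningless
  without an intercept).
* **multi** — DXA-covered total mass regressed on (fat, water, lung)
  volumes jointly. The zero intercept is what makes the coefficients
  interpretable as tissue densities. Standard errors come from the
  homoscedastic OLS formula `σ̂²(XᵀX)⁻¹`, σ̂² = SSres/(n−3). The regression
  direction is mass-on-volume throughout, since the coefficients carry kg/L
  units. A rank-deficient volume design raises `FitError`; a nonpositive
  fitted density (possible when a compartment's volume barely varies across
  subjects, as for lung) is returned faithfully with a warning rather than
  clipped.

## The synthetic study

The generator encodes the study conditions; its defaults are not tuning
knobs.

**Cohort.** Per-sex truncated normals for height and weight: women
160.5 ± 5.0 cm, 57.5 ± 13.1 kg; men 170.2 ± 5.0 cm, 69.3 ± 13.1 kg; bounds
150–183 cm and 37–103 kg; mixture 48 F : 42 M. These per-sex parameters are
chosen so the pooled cohort reproduces the target FDG-arm moments (weight
63 ± 14.4 kg, height 165 ± 7 cm, BMI ≈ 23.1). Because truncation at those
bounds would shift a naively parameterised mean by ~1 kg, the sampler
solves (brentq) for the underlying normal location whose *truncated* mean
equals the profile mean; the law-of-large-numbers test checks convergence
to the profile moments at n = 2000 within 3 SE. Height and weight are
sampled independently within sex, which leaves the BMI SD slightly wide
(~5.2 vs the ~4.5 typical of such cohorts) — acceptable for every analysis
here, all of which condition on BMI rather than assume its dispersion.
Dose is 221 ± 50 MBq and uptake time 72 ± 14 min (truncated); the PSMA
profile is all-male, 70.7 ± 8.4 kg, 314 ± 73 MBq, 141 ± 18 min.

**Body composition.** Fat fraction is an affine function of BMI with
sex-specific intercepts (women 0.025 + 0.012·BMI, men −0.065 + 0.012·BMI),
clipped to [5%, 55%] — a Deurenberg-style link giving ~30% fat for a
normal-BMI woman and ~23% for a man. Lung mass is fixed at 0.6 kg;
residual (off-coverage) mass is 8% of body weight; water mass is the
remainder. Nominal densities are fat 0.79, water 1.23, lung 0.20 kg/L, so
the calibration's noise-free recovery of exactly these values is a genuine
inverse-problem check.

**Phantom.** A quasi-ellipsoidal body of water voxels wearing a
subcutaneous fat shell, with two lung ellipsoids in the upper chest, in an
air background. Rather than thresholding analytic ellipsoids, voxels are
rank-ordered by an ellipsoidal norm and exactly the rounded per-compartment
counts are taken (fat = outermost body voxels; lungs = interior voxels
nearest the two lung centers), so each compartment's count × voxel volume ×
density matches its mass to within half a voxel-mass by construction. Ties
in the norm are broken by stable sort order, making phantoms bit-for-bit
reproducible. The default head-to-thigh grid is 96 × 80 × 260 voxels at
4 mm (~38 × 32 × 104 cm); the study pipeline defaults to 8 mm for speed —
volumetric accuracy depends only on the voxel volume relative to
compartment volumes, and at 8 mm the worst-case rounding is 0.5 voxel
≈ 0.3 kg of water.

**DXA.** Coverage-scaled true masses with multiplicative Gaussian noise,
default CV 2% (an error magnitude typical of repeat body-composition
measurements; the generator exposes it as a parameter). The composition's
compartments already exclude residual mass, so coverage 1.0 means
head-to-thigh.

**PET.** Organ activity is `level × D · DF / (water + lung mass)`: an organ
at level L has lean-normalized SUV ≈ L under perfect calibration, while
SUVbw inherits the subject's fat burden — the mechanism that makes SUVbw
BMI-dependent and SUV_dixon BMI-invariant is therefore present by
construction, not fitted. Fat voxels have exactly zero uptake before noise.
Default FDG levels (brain 3.7, liver 1.0, blood 0.58, muscle 0.35,
background 0.30, lung 0.20) mimic the whole-body FDG pattern on the
lean-SUV scale. Focal organs are carved from the water compartment: liver
and blood-pool spheres at fixed anatomical anchor points, brain/parotid and
thigh-muscle as extreme-z slabs gated to the head (z ≥ 0.5 normalized) and
thigh (z ≤ −0.5) regions so a small subject's brain cannot descend into the
chest; if a body is too small to reach a gate the plain extreme-z slab is
used. Two noise terms are separate and both default to off in
`simulate_pet`: per-organ lognormal biological variability (`organ_cv`; the
study pipeline uses 0.15 so cohort correlations are moderate rather than
≈1) and voxelwise additive Gaussian noise (`noise_sd`; pipeline default
0.3 kBq/mL, ~3% of liver activity), clipped at zero to keep activity maps
physical — at default levels the clipping probability is ~10⁻³ per fat/air
voxel and the induced mean shift is negligible.

What the generator deliberately does **not** emulate: anatomy beyond four
compartments, MR physics, partial-volume effects, Poisson counting noise,
scatter/randoms, reconstruction artifacts, lesions. Passing tests therefore
demonstrate the *analysis chain* (segmentation → volumetrics → calibration
→ LBM → SUV → statistics) is correct and self-consistent, not that the
method is robust to real-scanner physics.

## ROI conventions

Spheres include every voxel whose center lies within the radius
(deterministic, testable against the analytic volume; no partial-volume
weighting). The liver ROI is a 3 cm sphere, the blood pool 1 cm, per
PERCIST-style practice; at coarse grid spacings where a small sphere may
contain no voxel centers the pipeline degrades to the single nearest voxel.
SUVpeak is the mean over a 1 cm³ sphere (diameter 12.407 mm) centered on
the SUVmax voxel; a position-optimized variant (sweeping the sphere center)
is available but off by default. Threshold ROIs select voxels strictly
above the threshold and may legitimately be empty (warned, not an error).
The brain is measured with a threshold ROI (study default 2.5 SUV), all
other organs at the generator's known anchor centers — no anatomical
detection is attempted.

## Statistics

All inferential machinery is delegated to scipy.stats; the wrappers fix
conventions and validate degenerate inputs:

* Bland-Altman: bias = mean(reference − test); limits of agreement
  bias ∓ 2·SD (two whole sample SDs, not 1.96). Flipping the arguments
  negates the bias. Reference is always DXA in the agreement tables, so a
  method that *over*estimates lean mass shows a *negative* bias.
* Regression/correlation: OLS with two-sided slope p; Pearson r with
  t-distribution p. For the SUV-vs-BMI tables these two p-values coincide
  (univariate OLS), so one is reported.
* Paired and unpaired t tests are two-sided; the unpaired test pools
  variances. Zero-variance inputs raise instead of returning ±inf.
* One-way ANOVA across normalization methods treats the method groups as
  independent samples (a repeated-measures design would be more powerful
  but is out of scope); for two groups F = t² exactly.
* The KS normality check uses the sample mean and SD without the Lilliefors
  correction, so its p-values are conservative (it under-rejects); it is a
  screening diagnostic, not a gatekeeper.
* CV is the sample SD over the mean. BMI categories are the half-open bins
  [0, 18.5), [18.5, 25), [25, 30), [30, ∞) — the conventional strict
  inequalities leave the edges undefined, and here an edge value joins the
  upper category.
* No multiple-testing correction is applied anywhere.

## Pipeline and reproducibility

`run_study` derives independent substreams for cohort, DXA and PET noise
from the config seed via `SeedSequence.spawn`, so outputs are byte-identical
across runs of the same config (the manifest records the seed and a SHA-256
of the config, excluding the output directory). A zero-size cohort produces
a clean empty report. Any stage failure aborts with the stage named.
Problem sizes used by the shipped tests — n = 2000 for moment convergence,
n = 40 at 4 mm voxels for end-to-end lean-fraction recovery, n = 90 at 8 mm
for the cohort-level BMI analyses, 200 replicates for calibration coverage
— were chosen as the smallest sizes at which each check is statistically
meaningful.

## Known limitations

* Two-point-Dixon-style hard labels only; no continuous fat-fraction maps,
  so intra-voxel fat/water mixtures are invisible.
* Uniform density per tissue class; real organs vary.
* The lung density coefficient is weakly identified whenever lung volume
  barely varies across a cohort (in the generator it is constant), making
  its calibrated value noisy — visible in its large standard error, and in
  occasional nonpositive estimates under noise.
* The James formula is evaluated outside its validity range on request
  (flagged, not clipped); interpretation beyond the critical BMI is the
  caller's responsibility.
* DXA is treated as ground truth up to multiplicative noise; real DXA has
  systematic regional biases the generator does not model.
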