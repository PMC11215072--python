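# Methods

## Overview

The package models longitudinal amyloid PET in three coupled pieces:

1. **Representation.** A volumetric style-based generative model learns
   the appearance of PET scans. A mapping network `M` embeds a Gaussian
   noise vector `z` into an intermediate latent space `W` (`w = M(z)`);
   a synthesis network `G` renders a volume from `w`; an inversion
   encoder `E` maps a real volume back to `w = E(PET)` so every scan has
   a compact latent code.
2. **Quantification.** The cohort's latent table is compressed by
   centred PCA, `w ≈ w̄ + Σ_k v_k b_k`, and global SUVR (mean cortical
   uptake over mean cerebellar reference uptake) is predicted from the
   latents — full `w` or the first `K` principal scores `b` — by
   ordinary least squares, evaluated with bootstrap train/test splits.
3. **Progression.** In score space, disease dynamics follow the
   autonomous ODE `db/dt = V(b, c)` with covariates `c = (age, APOE-ε4
   allele count)`. `V` is estimated non-parametrically: finite-difference
   velocities from consecutive same-subject scan pairs are smoothed by
   one Gaussian-process regression per component; trajectories are
   forecast by forward Euler and rendered back to image space through
   `G(w̄ + Σ_k v_k b_k(t))`.

Because real amyloid cohorts are access-restricted, a phantom-brain
simulator with a *known* amyloid ODE and a *known* load→SUVR map stands
in for real data. Every downstream claim the test suite makes is checked
against this generative ground truth.

## Phantom cohort generator

A phantom volume is a sphere-based anatomy on a configurable grid:
a cortical shell (uptake encodes amyloid), a cerebellar reference sphere
(fixed unit intensity), near-zero ventricles, a white-matter-like
interior filler (0.7), and additive white acquisition noise
(σ = 0.02 by default, in reference-intensity units). Geometry is
expressed in grid fractions so the same spec scales from 16³ test grids
to the full 160×160×96 profile at 1.5 mm cubic voxels. By construction

    SUVR(a) = κ0 + κ1·a,     κ0 = κ1 = 1,

so SUVR spans [1, 2] as load `a` spans [0, 1] and the positivity
thresholds 1.1/1.2 fall in the realistic part of the scale. The
cortex/cerebellum masked-mean ratio is therefore an exact oracle for
what the pipeline should recover.

Amyloid load evolves by a logistic ODE

    da/dt = r · m^apoe4 · s_i · a · (1 − a/a_max),

with population base rate `r = 0.2/yr`, per-allele rate multiplier
`m = 1.5`, per-subject lognormal rate multiplier `s_i`
(σ_log = 0.3), and carrying capacity `a_max = 1`. The logistic form
captures the clinically observed plateau of amyloid accumulation; the
reference solution is integrated with a tight-tolerance adaptive RK
solver (rtol 1e-10), and the closed-form logistic solution is used as an
independent check in the tests. Baseline loads are Beta(1.2, 2.5)
distributed (most subjects sub-threshold, a tail of accumulators),
APOE-ε4 counts are drawn with probabilities (0.65, 0.27, 0.08), and
baseline ages are N(73, 7²) years — all chosen to resemble an aging
research cohort. Visit schedules draw 1–4 scans per subject with
probabilities (0.3, 0.3, 0.2, 0.2), i.e. a mean of 2.3 scans/subject,
on a 1-year grid with ±0.3 yr uniform jitter, exercising finite
differences with unequal Δt. Anatomy jitter (whole-brain translation,
clipped at 2 sd, and a small radial scale) varies geometry per subject
without breaking region disjointness, since all regions share the same
transform.

What the phantoms do **not** emulate: PET physics (scatter, attenuation,
partial-volume effects), anatomical detail beyond spheres, scanner
resolution differences, and spatial misalignment. Passing tests
therefore demonstrate that the pipeline machinery recovers known
dynamics from images whose signal-to-geometry relationship is simple;
they do not certify performance on clinical scans.

## Networks and training

No deep-learning framework is used; the networks run on an in-package
reverse-mode autodiff backbone over float32 numpy arrays (`nn.py`) with
exactly the required operators (3×3×3 "same" convolution, 2× average
pooling, 2× nearest-neighbour upsampling, dense layers, leaky ReLU,
softplus). All forward/backward passes are deterministic on one CPU, so
seeded training runs are bit-reproducible.

* **Mapping network**: `mapping_depth` fully connected layers
  (8 at full scale) with leaky ReLU (slope 0.2).
* **Synthesis network**: a learned constant volume; per level an
  upsampling, a per-channel style modulation `x ← x · (1 + A(w))` with a
  learned affine `A`, a 3×3×3 convolution, additive per-layer noise with
  learned strength, and leaky ReLU; a final linear 1-channel
  convolution. A single `w` modulates all layers (W space, not W+),
  matching the one-vector encoder. Per-layer noise buffers are sampled
  once at construction from the config seed and frozen thereafter, so
  synthesis is a deterministic function of `w`.
* **Discriminator**: mirror pyramid of conv + leaky ReLU + average
  pooling, dense scalar head.
* **Encoder**: five blocks of filtered downsampling (2× block
  averaging) followed by a 3×3×3 convolution and leaky ReLU, with filter
  depths 16, 32, 32, 32, 16, then a linear 96-unit dense head with no
  output activation (full-scale profile). On grids too small for five
  halvings the block count is reduced automatically with a logged
  warning (16³ supports four).

GAN training uses the non-saturating logistic loss with Adam
(β = (0, 0.99)). A zero-centred penalty on the critic's input gradient
at real samples is estimated by a randomized forward difference,
`E[(D(x+εu) − D(x))²]/ε²` with `u ~ N(0, I)`, whose expectation is the
squared gradient norm; this keeps the whole procedure first-order (no
double backprop) while still discouraging sharp critic gradients. It is
applied every 4th step with weight γ = 1. Style mixing and path-length
regularization are deliberately omitted: they serve image-fidelity goals
that are irrelevant to latent-trajectory modeling.

The encoder minimizes mean squared voxel error `||x − G(E(x))||²` with
the generator frozen (verified by checksum in the tests). Encoder inputs
are used as-is: phantom intensities are already expressed relative to
the cerebellar reference (unit mean), so a separate reference-region
normalization would be a near-identity operation; a normalization hook
is not included for that reason.

Checkpoints are single `.npz` archives containing every parameter array
plus an embedded JSON config, and round-trip bit-identically.

## PCA, SUVR regression and bootstrap

PCA is centred, components sorted by explained variance with a
deterministic sign convention (largest-magnitude coordinate positive).
The SUVR regressor is OLS with intercept via `lstsq`, which yields the
minimum-norm solution (with a logged warning) on rank-deficient designs.

Bootstrap evaluation draws random **subject-level** train/test splits —
all scans of a subject stay on one side — because with ~2.3 scans per
subject, per-scan splitting would leak longitudinal near-duplicates into
the test set and inflate performance. Defaults: test fraction 0.35,
1,000 splits for the headline report, 100 for the elbow curve;
95% intervals are percentile-based across splits. AUROC labels scans by
observed SUVR ≥ 1.1 (the amyloid-negative cutoff; the 1.1–1.2
intermediate band counts as positive by this convention, and the
threshold is configurable). Splits whose test set is single-class have
no AUROC; they are excluded from the AUROC aggregate and counted.

## Velocity field and integration

Finite-difference observations use consecutive same-subject scan pairs:
velocity `(b₂ − b₁)/Δt`, evaluated at the **pair midpoint** in state and
age (central-difference reasoning; a `start` evaluation mode exists for
sensitivity checks). Pairs with Δt < 0.25 yr are skipped (counted and
logged) because short-interval finite differences are dominated by
acquisition noise. Duplicate timestamps within a subject are an error.

Each velocity component gets an independent Gaussian process with an
anisotropic squared-exponential kernel plus white noise; inputs (scores
⊕ covariates) are z-scored and targets de-meaned before kernel
evaluation; hyperparameters are set by marginal-likelihood maximization
with seeded restarts. An `optimize=False` switch keeps the initial
hyperparameters — used by the exact-interpolation tests, because on
perfectly linear targets the marginal likelihood drives the length
scales to a near-degenerate optimum where the interpolation identity
holds only to ~1e-5.

Forecasting is forward Euler, `b_{n+1} = b_n + h·V(b_n, c(t_n))`, with
the age covariate advancing with integration time (a frozen age would be
inconsistent over 15-year horizons). Default step h = 0.1 yr for plots
and 0.05–0.01 yr for quantitative work; the integrator is first-order,
verified by the error-halving test against the closed-form exponential
fixture. A non-finite state aborts with the step index and last finite
state. Image trajectories render `G(w̄ + Σ v_k b_k(t))` with
`b(0) = project(E(baseline))`; at t = 0 this is bit-identical to the
reconstruction chain by construction.

Phase plots color baselines by positivity (SUVR < 1.1 negative, > 1.2
positive, intermediate between), with 5-year thin trajectories from all
baselines and 15-year thick ones for selected subjects. Difference
panels use a symmetric window (±0.4 by default, configurable).

## Pipeline profiles and problem sizes

The `tiny` profile — 64 subjects, 16³ grids, a 32-dimensional latent
space, 300 GAN steps and 400 encoder steps — is the package's default
working size: large enough that the encoder's latents rank-order SUVR
reliably (held-out Spearman ≈ 0.9 in the shipped configuration) and the
fitted velocity field separates accumulators from stable subjects, small
enough for interactive single-CPU use. Training length was fixed at a
point where the adversarial game reliably couples the latent space to
cortical intensity; adversarial convergence is not monotone in step
count at this scale, so "more steps" is not automatically better and
the encoder's reconstruction quality (not the GAN loss) is the
practical convergence signal. The phantom reference region is
deliberately generous (≈0.7% of the grid) because rendered SUVR divides
by its mean — a reference of a few voxels would make the oracle's
denominator generator-noise-dominated. The `paper-scale` profile
(160×160×96 at 1.5 mm, w of length 96, 8-layer mapping network, 1,259
subjects) is config-complete and architecture-checked but GPU-scale; the
test suite exercises its construction, not its training.

One global seed fans out to per-stage seeds by CRC32 hashing, so each
stage is reproducible in isolation; stage manifests record config
hashes, seeds and artifact paths.

## Known limitations

* The generative model is validated on sphere-based phantoms; nothing
  here measures fidelity on real PET (no FID-style metrics by design).
* GP components are independent; correlated velocity noise across
  components is not modelled.
* Forward Euler is the only integrator (first-order), chosen for
  transparency; quantitative work uses small steps instead of
  higher-order schemes.
* The covariate model is minimal (age, APOE-ε4 count as a numeric
  0/1/2 regressor); no interactions, no one-hot coding.
* Velocity observations assume the state fully determines progression
  (autonomous ODE); diverging trajectories from identical states cannot
  be represented.
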