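# amyloid-latent-dyn

Latent-space quantification and progression modeling of amyloid PET.

Brain amyloid-β accumulation — imaged with tracers such as
¹⁸F-Florbetapir and summarized by the standardized uptake value ratio
(SUVR: mean cortical uptake / mean cerebellar reference uptake) —
evolves over decades and is usually observed in just a handful of
irregularly spaced scans per person. This package is for researchers who
want a single generative framework that (a) compresses volumetric PET
scans into a low-dimensional latent code, (b) quantifies global SUVR
directly from that code, and (c) learns a continuous model of amyloid
dynamics that can forecast and *render* a subject's future scans.

The pipeline:

1. **3D style-based GAN** — a mapping network `M` embeds `z ~ N(0, I)`
   into an intermediate latent space `W` (`w = M(z)`); a synthesis
   network `G` renders volumes from `w`; a discriminator drives
   adversarial training.
2. **Inversion encoder** — `E` maps a real scan to `w = E(PET)`,
   trained by voxel-MSE `‖PET − G(E(PET))‖²` against the frozen `G`.
3. **PCA + linear SUVR regression** — `w ≈ w̄ + Σₖ vₖ bₖ`; OLS predicts
   SUVR from `w` or from the first `K` principal scores, evaluated by
   bootstrap subject-level train/test splits (RMSE, MAE, AUROC of
   amyloid-positivity classification) and an elbow curve over `K`.
4. **Non-parametric ODE progression model** — velocities
   `db/dt = V(b, c)` (covariates: age, APOE-ε4 count) estimated from
   finite differences of consecutive same-subject scans, smoothed by one
   Gaussian-process regressor per component, integrated by forward Euler
   and rendered back through `G` as synthetic image trajectories.

Because real amyloid cohorts are access-restricted, the package ships a
**phantom-brain cohort simulator** with known logistic amyloid dynamics
(`da/dt = r·m^apoe4·a(1−a/a_max)`) and an exact load→SUVR map, so every
stage can be built and validated against ground truth. See
`docs/methods.md` for the full model description.

## Worked example

Run the full tiny-profile workflow (64 phantom subjects, 16³ grids,
single CPU, a few minutes):

```bash
amyloid-latent-dyn all --seed 1
```

or stage by stage from Python:

```python
from amyloid_latent_dyn.cli import default_config, run_stage

cfg = default_config("tiny")
cfg["paths"]["output_dir"] = "runs/demo"
cfg["seed"] = 1
for stage in ("simulate-cohort", "train-gan", "train-encoder", "embed",
              "evaluate-suvr", "fit-pca", "elbow", "fit-dynamics"):
    run_stage(stage, cfg)
print(open("runs/demo/suvr_bootstrap.txt").read())
```

which prints (seed 1):

```
bootstrap over 100 subject-level splits (test fraction 0.35)
  RMSE: 0.4601 (0.0566, 2.1035)
  MAE: 0.1741 (0.0454, 0.6541)
  AUROC: 0.9475 (0.8221, 1.0000)
```

Ranking held-out scans by SUVR predicted from the full 32-dimensional
latent vector separates amyloid-positive from amyloid-negative scans
(threshold 1.1) with AUROC ≈0.95, but the absolute error is unstable:
with only ~42 training subjects per split, OLS on the full latent
overfits badly on some splits (note the wide 95% percentile band).
This is exactly what the PCA stage is for — the elbow curve
(`runs/demo/elbow.csv`) from the same run shows the error of the
dimension-reduced regression:

```
 K  rmse_mean  rmse_ci_low  rmse_ci_high
 1   0.131162     0.100673      0.168197
 2   0.114530     0.083011      0.153344
 3   0.094451     0.073374      0.117588
 5   0.131705     0.071150      0.329842
 8   0.077133     0.045059      0.166652
```

i.e. ≈0.08–0.13 SUVR on a phantom scale that runs 1–2, an order of
magnitude tighter than the full-latent fit at this cohort size.

After `fit-dynamics`, 4-year synthetic image trajectories for a subject
are rendered with the `render-trajectory` stage (NIfTI series plus a
difference panel), and `plot-dynamics` draws the phase portrait of the
fitted velocity field on a pair of principal components, with baselines
colored by amyloid positivity (SUVR < 1.1 negative / > 1.2 positive).

On this run, rendering accumulating subjects (APOE-ε4 carriers with
baseline SUVR in the steep part of the logistic) 4 years forward raises
their oracle-measured SUVR by ≈ +0.18 on average, while a null-dynamics
cohort (rate 0) drifts by < 0.001 — the fitted field moves latent codes
in the amyloid direction only when the underlying dynamics do.

The `paper-scale` profile (160×160×96 voxels at 1.5 mm, 96-dimensional
latents, 8-layer mapping network) is configuration-complete but
GPU-scale; the test suite checks its architecture, not its training.

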