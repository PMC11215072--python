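"""Synthetic longitudinal phantom-brain cohorts with known amyloid dynamics.

Each phantom volume is a simple anatomical model of an amyloid PET scan:
a spherical cortical shell whose mean intensity encodes amyloid load, a
cerebellar reference sphere of fixed intensity, near-zero ventricles, and
optional additive Gaussian acquisition noise.  Global SUVR — the mean
cortical uptake divided by the mean reference uptake — is therefore known
exactly by construction, which makes the phantoms a ground-truth oracle
for every downstream stage (encoding, regression, progression modeling).

Amyloid load a(t) evolves per subject by a logistic ODE

    da/dt = r * m^apoe4 * s_i * a * (1 - a / a_max)

where r is the population base rate (per year), m the per-allele APOE-e4
rate multiplier, and s_i a per-subject lognormal rate multiplier.  SUVR is
affine in load: SUVR = kappa0 + kappa1 * a.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PhantomSpec",
    "GroundTruthDynamics",
    "build_phantom",
    "region_masks",
    "compute_reference_suvr",
    "simulate_cohort",
]


class PhantomGeometryError(ValueError):
    """A region does not fit inside the grid or regions overlap."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of the phantom brain.

    Region geometry is expressed in fractions of the grid so the same spec
    scales from tiny test grids to the full 160x160x96 profile.  Radii are
    fractions of the smallest grid axis; centers are fractions per axis.
    """

    grid_shape: tuple = (32, 32, 24)
    voxel_size_mm: float = 1.5
    brain_center: tuple = (0.5, 0.5, 0.62)
    shell_radii: tuple = (0.18, 0.26)  # inner, outer (cortical shell)
    ventricle_radius: float = 0.08
    cerebellum_center: tuple = (0.5, 0.5, 0.18)
    cerebellum_radius: float = 0.11
    interior_intensity: float = 0.7  # white-matter-like filler
    reference_intensity: float = 1.0  # cerebellum mean (SUVR denominator)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise PhantomGeometryError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        masks = region_masks(self)
        for name in ("cortex", "cerebellum"):
            if not masks[name].any():
                raise PhantomGeometryError(f"region '{name}' is empty on grid {self.grid_shape}")
        overlap = (
            masks["cortex"].astype(int)
            + masks["cerebellum"].astype(int)
            + masks["ventricles"].astype(int)
        )
        if (overlap > 1).any():
            raise PhantomGeometryError("cortex / cerebellum / ventricle masks overlap")


def _sphere(shape, center_frac, radius_frac, jitter=None):
    """Boolean ball; center in grid fractions, radius in fractions of min axis."""
    shape = np.asarray(shape, dtype=float)
    center = np.asarray(center_frac, dtype=float) * (shape - 1)
    radius = float(radius_frac) * shape.min()
    if jitter is not None:
        center = center + jitter[:3]
        radius = radius * jitter[3]
    grids = np.ogrid[tuple(slice(0, int(s)) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    if radius < 0.5:
        raise PhantomGeometryError("region radius below half a voxel")
    for c, s in zip(center, shape):
        if c - radius < -0.5 or c + radius > s - 0.5:
            raise PhantomGeometryError("region extends outside the grid")
    return d2 <= radius**2


def region_masks(spec: PhantomSpec, jitter: np.ndarray | None = None) -> dict:
    """Cortex shell, cerebellum, ventricle and interior masks for a spec.

    `jitter` is an optional (4,) array: voxel offsets (dx, dy, dz) and a
    radial scale applied to the whole brain geometry (per-subject anatomy).
    """
    shape = spec.grid_shape
    try:
        outer = _sphere(shape, spec.brain_center, spec.shell_radii[1], jitter)
        inner = _sphere(shape, spec.brain_center, spec.shell_radii[0], jitter)
        vent = _sphere(shape, spec.brain_center, spec.ventricle_radius, jitter)
        cereb = _sphere(shape, spec.cerebellum_center, spec.cerebellum_radius, jitter)
    except PhantomGeometryError as e:
        raise PhantomGeometryError(f"phantom geometry error on grid {shape}: {e}") from e
    cortex = outer & ~inner
    interior = inner & ~vent
    return {
        "cortex": cortex,
        "cerebellum": cereb & ~outer,
        "ventricles": vent,
        "interior": interior,
    }


def build_phantom(
    spec: PhantomSpec,
    load: float,
    dynamics: "GroundTruthDynamics | None" = None,
    anatomy_jitter: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render one phantom PET volume at a given amyloid load.

    The cerebellum mean equals ``spec.reference_intensity``, the cortical
    shell mean equals ``reference * (kappa0 + kappa1 * load)``, ventricles
    are zero, and N(0, noise_sigma^2) noise is added everywhere.
    Deterministic given (spec, load, jitter, seed).
    """
    dyn = dynamics or GroundTruthDynamics()
    if not (0.0 <= load <= dyn.a_max):
        raise ValueError(f"load {load} outside [0, {dyn.a_max}]")
    masks = region_masks(spec, anatomy_jitter)
    # float64 in memory so the load -> SUVR -> load round trip is exact;
    # NIfTI storage downcasts to float32
    vol = np.zeros(spec.grid_shape, dtype=np.float64)
    suvr = dyn.kappa0 + dyn.kappa1 * load
    vol[masks["interior"]] = spec.interior_intensity * spec.reference_intensity
    vol[masks["cortex"]] = suvr * spec.reference_intensity
    vol[masks["cerebellum"]] = spec.reference_intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, vol.shape)
    return vol


def compute_reference_suvr(volume: np.ndarray, masks: dict) -> float:
    """Mean cortical intensity over mean reference intensity.

    This is the ground-truth SUVR oracle: the simplified analogue of the
    composite-cortex / reference-region ratio used in amyloid PET.
    """
    for name in ("cortex", "cerebellum"):
        if name not in masks or not np.asarray(masks[name]).any():
            raise ValueError(f"empty or missing mask: '{name}'")
    ref = float(volume[masks["cerebellum"]].mean())
    if ref == 0.0:
        raise ZeroDivisionError("reference region 'cerebellum' has zero mean")
    return float(volume[masks["cortex"]].mean()) / ref


@dataclasses.dataclass(frozen=True)
class GroundTruthDynamics:
    """Parameters of the logistic amyloid-load ODE and the load->SUVR map."""

    base_rate: float = 0.2  # r, per year
    a_max: float = 1.0
    apoe_multiplier: float = 1.5  # rate multiplier per APOE-e4 allele
    kappa0: float = 1.0  # SUVR at zero load
    kappa1: float = 1.0  # SUVR per unit load
    subject_rate_sigma: float = 0.3  # lognormal sd of per-subject multiplier

    def __post_init__(self):
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.a_max <= 0:
            raise ValueError("a_max must be > 0")
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be > 0 (SUVR at zero load)")

    def rate(self, apoe4_count: int, subject_multiplier: float = 1.0) -> float:
        return self.base_rate * self.apoe_multiplier**apoe4_count * subject_multiplier

    def solve_load(self, a0: float, rate: float, times: np.ndarray) -> np.ndarray:
        """Reference integration of the logistic ODE at requested times."""
        times = np.asarray(times, dtype=float)
        if a0 == 0.0 or rate == 0.0 or times.size == 0 or times.max() == 0.0:
            return np.full_like(times, a0)
        sol = solve_ivp(
            lambda t, a: rate * a * (1.0 - a / self.a_max),
            (0.0, float(times.max())),
            [a0],
            t_eval=times,
            rtol=1e-10,
            atol=1e-12,
            max_step=0.05,
        )
        return sol.y[0]

    def suvr(self, load):
        return self.kappa0 + self.kappa1 * np.asarray(load)


DEFAULT_VISIT_COUNT_PROBS = {1: 0.3, 2: 0.3, 3: 0.2, 4: 0.2}  # mean 2.3 scans
DEFAULT_APOE_PROBS = (0.65, 0.27, 0.08)


def _draw_visit_times(rng, n_visits, jitter=0.3, min_dt=0.3):
    """Irregular visits: a 1-year grid with uniform jitter, baseline at 0."""
    times = [0.0]
    for j in range(1, n_visits):
        t = j * 1.0 + rng.uniform(-jitter, jitter)
        t = max(t, times[-1] + min_dt)
        times.append(t)
    return np.asarray(times)


def simulate_cohort(
    n_subjects: int,
    out_dir: str | Path,
    dynamics: GroundTruthDynamics | None = None,
    spec: PhantomSpec | None = None,
    visit_count_probs: dict | None = None,
    apoe_probs: tuple = DEFAULT_APOE_PROBS,
    seed: int = 0,
    anatomy_jitter_sd: float = 0.5,
    write_volumes: bool = True,
) -> pd.DataFrame:
    """Simulate a longitudinal phantom cohort and write it to disk.

    Per subject: draws APOE-e4 count, baseline age, baseline load and a
    per-subject rate multiplier; evolves load by the logistic ODE with a
    reference integrator; renders one phantom volume per visit (NIfTI-1,
    RAS, float32) and appends a row per scan to the metadata table.

    Returns the metadata table (also written as ``cohort.csv``); a JSON
    sidecar ``ground_truth.json`` stores the dynamics parameters and the
    per-scan true loads for recovery tests.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dyn = dynamics or GroundTruthDynamics()
    spec = spec or PhantomSpec()
    probs = visit_count_probs or DEFAULT_VISIT_COUNT_PROBS
    counts = np.array(sorted(probs))
    pvals = np.array([probs[c] for c in counts], dtype=float)
    pvals = pvals / pvals.sum()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rows, truth_scans = [], []
    for i in range(n_subjects):
        sid = f"sub-{i:04d}"
        apoe = int(rng.choice([0, 1, 2], p=apoe_probs))
        age0 = float(rng.normal(73.0, 7.0))
        a0 = float(np.clip(rng.beta(1.2, 2.5) * dyn.a_max, 0.0, dyn.a_max))
        smult = float(rng.lognormal(0.0, dyn.subject_rate_sigma))
        n_visits = int(rng.choice(counts, p=pvals))
        times = _draw_visit_times(rng, n_visits)
        loads = dyn.solve_load(a0, dyn.rate(apoe, smult), times)
        # whole-brain translation (voxels, clipped at 2 sd) and radial scale;
        # one draw per subject so all regions move together
        shift = np.clip(
            rng.normal(0.0, anatomy_jitter_sd, 3),
            -2 * anatomy_jitter_sd, 2 * anatomy_jitter_sd,
        )
        scale = float(np.clip(rng.lognormal(0.0, 0.02), 0.95, 1.06))
        jitter = np.concatenate([shift, [scale]])
        diagnosis = "CN" if a0 < 0.1 else ("MCI" if a0 < 0.4 else "AD")
        for j, (t, a) in enumerate(zip(times, loads)):
            scan_seed = int(rng.integers(0, 2**31 - 1))
            path = out_dir / f"{sid}_scan{j}.nii"
            if write_volumes:
                vol = build_phantom(spec, float(a), dyn, jitter, scan_seed)
                affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
                nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
            rows.append(
                {
                    "subject_id": sid,
                    "scan_time_years": float(t),
                    "age": age0 + float(t),
                    "apoe4_count": apoe,
                    "suvr": float(dyn.suvr(a)),
                    "diagnosis": diagnosis,
                    "nifti_path": str(path),
                }
            )
            truth_scans.append(
                {"subject_id": sid, "scan_time_years": float(t), "true_load": float(a),
                 "scan_seed": scan_seed}
            )

    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "cohort.csv", index=False)
    sidecar = {
        "dynamics": dataclasses.asdict(dyn),
        "spec": {**dataclasses.asdict(spec)},
        "seed": seed,
        "scans": truth_scans,
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return table


def load_cohort_volumes(table: pd.DataFrame) -> np.ndarray:
    """Stack the cohort's NIfTI volumes into an (n_scans, D, H, W) array."""
    vols = [np.asarray(nib.load(p).dataobj, dtype=np.float32) for p in table["nifti_path"]]
    return np.stack(vols)
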