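"""Non-parametric ODE progression model in principal-score space.

The latent state of a scan is its vector of principal scores b.  Disease
progression is modelled as db/dt = V(b, c) where c are covariates (age,
APOE-e4 allele count) and V is unknown.  V is estimated non-parametrically:

1. velocity observations are finite differences of principal scores
   between consecutive scans of the same subject, evaluated at the pair
   midpoint in state and age;
2. each component of V is regressed with an independent Gaussian process
   (anisotropic squared-exponential kernel + white noise, hyperparameters
   by marginal-likelihood maximization);
3. trajectories are forecast by forward Euler integration, with the age
   covariate advancing with integration time;
4. latent trajectories are projected back to W and rendered to synthetic
   volumes by the generator (image trajectory at time t is
   G(w_bar + sum_k v_k b_k(t)), with b(0) from the encoded baseline).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .latent_quant import NEGATIVE_SUVR, POSITIVE_SUVR, PcaModel, back_project, project

__all__ = [
    "finite_difference_velocities",
    "GPFieldConfig",
    "VelocityFieldModel",
    "fit_velocity_field",
    "predict_velocity",
    "Trajectory",
    "integrate_trajectory",
    "generate_image_trajectory",
    "plot_dynamics",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_DT = 0.25  # years; shorter inter-scan gaps give too-noisy velocities


def finite_difference_velocities(
    score_table: pd.DataFrame,
    score_cols: list[str] | None = None,
    min_dt: float = DEFAULT_MIN_DT,
    eval_point: str = "midpoint",
) -> pd.DataFrame:
    """Velocity observations from consecutive same-subject scan pairs.

    `score_table` needs columns subject_id, scan_time_years, age,
    apoe4_count and the principal-score columns (default: all columns
    named ``b_*``).  Each consecutive pair within a subject yields one
    observation: velocity (b2-b1)/(t2-t1), evaluated at the pair midpoint
    (state and age) or at the pair start if ``eval_point="start"``.
    Pairs with dt below `min_dt` are skipped (count logged); duplicate
    timestamps within a subject raise.
    """
    if eval_point not in ("midpoint", "start"):
        raise ValueError("eval_point must be 'midpoint' or 'start'")
    if score_cols is None:
        score_cols = [c for c in score_table.columns if c.startswith("b_")]
    if not score_cols:
        raise ValueError("no principal-score columns found (expected b_*)")

    dups = []
    rows = []
    n_skipped = 0
    for sid, g in score_table.groupby("subject_id", sort=True):
        g = g.sort_values("scan_time_years")
        t = g["scan_time_years"].to_numpy(dtype=float)
        if np.unique(t).size != t.size:
            dups.append(sid)
            continue
        b = g[score_cols].to_numpy(dtype=float)
        age = g["age"].to_numpy(dtype=float)
        apoe = int(g["apoe4_count"].iloc[0])
        for j in range(len(t) - 1):
            dt = t[j + 1] - t[j]
            if dt < min_dt:
                n_skipped += 1
                continue
            vel = (b[j + 1] - b[j]) / dt
            if eval_point == "midpoint":
                state = 0.5 * (b[j] + b[j + 1])
                a = 0.5 * (age[j] + age[j + 1])
            else:
                state, a = b[j], age[j]
            row = {"subject_id": sid, "pair_index": j, "dt": dt, "age": a,
                   "apoe4_count": apoe}
            row.update({c: state[k] for k, c in enumerate(score_cols)})
            row.update({f"v_{c}": vel[k] for k, c in enumerate(score_cols)})
            rows.append(row)
    if dups:
        raise ValueError(f"duplicate scan timestamps for subjects: {dups}")
    if n_skipped:
        logger.info("skipped %d pairs with dt < %.3g years", n_skipped, min_dt)
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_skipped
    out.attrs["score_cols"] = list(score_cols)
    return out


@dataclasses.dataclass(frozen=True)
class GPFieldConfig:
    covariates: tuple = ("age", "apoe4_count")
    signal_variance: float = 1.0
    length_scale: float = 1.0
    noise_variance: float = 1e-2
    noise_bounds: tuple = (1e-8, 1e2)
    n_restarts: int = 2
    optimize: bool = True  # False: keep the initial hyperparameters (exact GP interpolation)


@dataclasses.dataclass
class VelocityFieldModel:
    """K independent GP regressors for the components of V(b, c)."""

    gps: list
    score_cols: list
    covariates: tuple
    input_mean: np.ndarray
    input_sd: np.ndarray
    target_mean: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.score_cols)

    def _design(self, b: np.ndarray, c: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.atleast_2d(b), np.atleast_2d(c)])
        return (X - self.input_mean) / self.input_sd

    def save(self, path: str | Path):
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "VelocityFieldModel":
        return joblib.load(path)


def fit_velocity_field(
    observations: pd.DataFrame,
    config: GPFieldConfig | None = None,
    seed: int = 0,
) -> VelocityFieldModel:
    """Fit one GP per velocity component on (state + covariates) inputs.

    Inputs are z-scored and targets de-meaned per component before kernel
    evaluation; hyperparameters (signal variance, per-dimension length
    scales, noise variance) are optimized by marginal likelihood with
    seeded restarts.
    """
    config = config or GPFieldConfig()
    score_cols = observations.attrs.get("score_cols") or [
        c for c in observations.columns if c.startswith("b_")
    ]
    if len(observations) < 5:
        raise ValueError("need at least 5 velocity observations")
    b = observations[score_cols].to_numpy(dtype=float)
    if np.allclose(b, b[0]):
        raise ValueError("degenerate observations: all states identical")
    cov = (
        observations[list(config.covariates)].to_numpy(dtype=float)
        if config.covariates
        else np.empty((len(observations), 0))
    )
    X = np.column_stack([b, cov])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    targets = observations[[f"v_{c}" for c in score_cols]].to_numpy(dtype=float)
    tmean = targets.mean(axis=0)

    gps = []
    for k in range(len(score_cols)):
        kernel = ConstantKernel(config.signal_variance, (1e-4, 1e4)) * RBF(
            np.full(Xs.shape[1], config.length_scale), (1e-2, 1e3)
        ) + WhiteKernel(config.noise_variance, config.noise_bounds)
        gp = GaussianProcessRegressor(
            kernel=kernel,
            optimizer="fmin_l_bfgs_b" if config.optimize else None,
            n_restarts_optimizer=config.n_restarts if config.optimize else 0,
            random_state=seed + k,
            normalize_y=False,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xs, targets[:, k] - tmean[k])
        gps.append(gp)
    return VelocityFieldModel(
        gps, list(score_cols), tuple(config.covariates), mean, sd, tmean
    )


def predict_velocity(
    b: np.ndarray, c: np.ndarray, model: VelocityFieldModel
) -> tuple[np.ndarray, np.ndarray]:
    """GP posterior mean and variance of each velocity component at (b, c)."""
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if b.shape[1] != model.n_components:
        raise ValueError(f"state dim {b.shape[1]} != K={model.n_components}")
    if c.shape[1] != len(model.covariates):
        raise ValueError(
            f"covariate dim {c.shape[1]} != {len(model.covariates)} "
            f"({model.covariates})"
        )
    Xs = model._design(b, c)
    means, vars_ = [], []
    for k, gp in enumerate(model.gps):
        m, sd = gp.predict(Xs, return_std=True)
        means.append(m + model.target_mean[k])
        vars_.append(sd**2)
    mean = np.column_stack(means)
    var = np.column_stack(vars_)
    if b.shape[0] == 1:
        return mean[0], var[0]
    return mean, var


@dataclasses.dataclass
class Trajectory:
    times: np.ndarray  # years from start, strictly increasing, times[0] == 0
    states: np.ndarray  # (n_times, K)
    covariates: np.ndarray  # covariates at start (age advances internally)
    step: float

    def state_at(self, t: float) -> np.ndarray:
        """State at the grid point nearest to t."""
        return self.states[int(np.argmin(np.abs(self.times - t)))]


def integrate_trajectory(
    b0: np.ndarray,
    c: np.ndarray,
    duration: float,
    step: float,
    model: VelocityFieldModel | None = None,
    field=None,
    advance_age: bool = True,
) -> Trajectory:
    """Forward Euler: b_{n+1} = b_n + h * V(b_n, c(t_n)).

    `field` may inject an analytic velocity function ``f(b, c) -> db/dt``
    (bypassing the GP) for validation.  The first covariate is treated as
    age and advances with integration time unless `advance_age` is False.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if field is None:
        if model is None:
            raise ValueError("provide a fitted model or an analytic field")
        field = lambda b, cc: predict_velocity(b, cc, model)[0]
    b = np.asarray(b0, dtype=float).copy()
    c = np.asarray(c, dtype=float).copy()
    times = [0.0]
    states = [b.copy()]
    t = 0.0
    n = 0
    while t < duration - 1e-12:
        h = min(step, duration - t)
        ct = c.copy()
        if advance_age and ct.size:
            ct[0] = c[0] + t
        v = np.asarray(field(b, ct), dtype=float).reshape(b.shape)
        b = b + h * v
        if not np.all(np.isfinite(b)):
            raise RuntimeError(
                f"non-finite state at step {n} (t={t + h:.4g}); "
                f"last finite state {states[-1]}"
            )
        t += h
        n += 1
        times.append(t)
        states.append(b.copy())
    return Trajectory(np.asarray(times), np.asarray(states), c, step)


def generate_image_trajectory(
    baseline_volume: np.ndarray,
    c: np.ndarray,
    times,
    enc,
    gan,
    pca: PcaModel,
    model: VelocityFieldModel | None = None,
    field=None,
    step: float = 0.1,
) -> dict:
    """Synthetic image evolution of one subject from a baseline scan.

    b0 = project(E(baseline)); the velocity field is integrated to each
    requested time t and the volume G(w_bar + sum_k v_k b_k(t)) rendered.
    At t=0 this is exactly G(back_project(project(E(baseline)))).  Returns
    times, latent states, rendered volumes and difference volumes vs t=0.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be sorted, strictly increasing, starting at 0")
    w0 = enc.encode(baseline_volume)
    b0 = project(w0, pca)
    if times[-1] > 0:
        traj = integrate_trajectory(b0, c, float(times[-1]), step, model, field)
        states = np.stack([b0 if t == 0 else traj.state_at(t) for t in times])
    else:
        states = b0[None]
    volumes = [
        np.asarray(gan.synthesize(back_project(b, pca)), dtype=np.float32)
        for b in states
    ]
    diffs = [v - volumes[0] for v in volumes]
    return {"times": times, "states": states, "volumes": volumes, "differences": diffs}


def _positivity_color(suvr: float) -> str:
    if suvr < NEGATIVE_SUVR:
        return "tab:blue"  # amyloid negative
    if suvr > POSITIVE_SUVR:
        return "tab:red"  # amyloid positive
    return "tab:green"  # intermediate


def plot_dynamics(
    score_table: pd.DataFrame,
    model: VelocityFieldModel,
    path: str | Path,
    pc_pair: tuple = (0, 1),
    short_horizon: float = 5.0,
    long_horizon: float = 15.0,
    long_subjects: list | None = None,
    step: float = 0.1,
) -> Path:
    """Phase plot of the fitted dynamics on a pair of principal components.

    Baseline scores are scattered and colored by amyloid positivity
    (negative SUVR < 1.1 blue, positive > 1.2 red, intermediate green);
    thin semi-transparent lines show `short_horizon` years of evolution
    from every baseline, thick lines `long_horizon` years for the listed
    subjects.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    score_cols = model.score_cols
    i, j = pc_pair
    if max(i, j) >= len(score_cols):
        raise ValueError(f"pc_pair {pc_pair} out of range for K={len(score_cols)}")
    base = score_table.sort_values("scan_time_years").groupby("subject_id").first()
    long_subjects = list(long_subjects or [])
    unknown = set(long_subjects) - set(base.index)
    if unknown:
        raise ValueError(f"unknown subject ids: {sorted(unknown)}")

    fig, ax = plt.subplots(figsize=(6, 5))
    for sid, row in base.iterrows():
        b0 = row[score_cols].to_numpy(dtype=float)
        c = np.array([row["age"], row["apoe4_count"]], dtype=float)[
            : len(model.covariates)
        ]
        col = _positivity_color(float(row["suvr"]))
        traj = integrate_trajectory(b0, c, short_horizon, step, model)
        ax.plot(traj.states[:, i], traj.states[:, j], color=col, lw=0.6, alpha=0.4)
        ax.plot(b0[i], b0[j], "o", color=col, ms=3)
    for sid in long_subjects:
        row = base.loc[sid]
        b0 = row[score_cols].to_numpy(dtype=float)
        c = np.array([row["age"], row["apoe4_count"]], dtype=float)[
            : len(model.covariates)
        ]
        traj = integrate_trajectory(b0, c, long_horizon, step, model)
        ax.plot(
            traj.states[:, i], traj.states[:, j],
            color=_positivity_color(float(row["suvr"])), lw=2.0,
        )
    ax.set_xlabel(f"PC {i + 1}")
    ax.set_ylabel(f"PC {j + 1}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
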