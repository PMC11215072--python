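"""PCA compression of latent tables and SUVR quantification.

A latent table holds one row per scan: the intermediate latent vector w
of length L plus subject/time metadata.  This module provides

* centred PCA of the latent table, ``w ~ w_bar + sum_k v_k b_k``, with a
  deterministic sign convention,
* ordinary least squares regression from latents (full W or K principal
  scores) to global SUVR,
* a bootstrap evaluation over random subject-level train/test splits
  reporting RMSE, MAE and the AUROC of amyloid-positivity classification,
  with percentile confidence intervals,
* the elbow curve of prediction error versus number of principal
  components.

Splits are at subject level — all scans of a subject stay on the same
side — to avoid longitudinal leakage between train and test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

__all__ = [
    "PcaModel",
    "SuvrRegressor",
    "BootstrapReport",
    "fit_pca",
    "project",
    "back_project",
    "fit_suvr_regression",
    "predict_suvr",
    "bootstrap_evaluate",
    "elbow_curve",
]

logger = logging.getLogger(__name__)

#: SUVR below this is amyloid negative; above POSITIVE_SUVR is positive.
NEGATIVE_SUVR = 1.1
POSITIVE_SUVR = 1.2


@dataclasses.dataclass
class PcaModel:
    mean: np.ndarray  # w_bar, length L
    components: np.ndarray  # (K, L), orthonormal rows
    explained_variance_ratio: np.ndarray  # length K, nonincreasing

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self, path: str | Path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean": self.mean.tolist(),
                    "components": self.components.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["mean"]),
            np.asarray(d["components"]),
            np.asarray(d["explained_variance_ratio"]),
        )


def fit_pca(latents: np.ndarray, n_components: int) -> PcaModel:
    """Centred PCA of an (n, L) latent table.

    Components are sorted by explained variance and sign-fixed so the
    largest-magnitude coordinate of each component is positive.
    """
    latents = np.asarray(latents, dtype=float)
    n, L = latents.shape
    if n_components > L:
        raise ValueError(f"n_components={n_components} exceeds latent dimension L={L}")
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} rows, got {n}")
    p = PCA(n_components=n_components, svd_solver="full")
    p.fit(latents)
    comps = p.components_.copy()
    for k in range(comps.shape[0]):  # deterministic sign convention
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    return PcaModel(p.mean_.copy(), comps, p.explained_variance_ratio_.copy())


def project(w: np.ndarray, model: PcaModel) -> np.ndarray:
    """Principal scores b_k = v_k . (w - w_bar)."""
    w = np.asarray(w, dtype=float)
    if w.shape[-1] != model.mean.shape[0]:
        raise ValueError(f"latent length {w.shape[-1]} != model L {model.mean.shape[0]}")
    return (w - model.mean) @ model.components.T


def back_project(b: np.ndarray, model: PcaModel) -> np.ndarray:
    """w = w_bar + sum_k v_k b_k (the point on the PCA hyperplane)."""
    b = np.asarray(b, dtype=float)
    if b.shape[-1] != model.n_components:
        raise ValueError(f"score length {b.shape[-1]} != K {model.n_components}")
    return model.mean + b @ model.components


@dataclasses.dataclass
class SuvrRegressor:
    weights: np.ndarray
    intercept: float
    feature_space: str = "latent"  # "latent" (full W) or "pca"

    def to_json(self, path: str | Path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "weights": self.weights.tolist(),
                    "intercept": self.intercept,
                    "feature_space": self.feature_space,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SuvrRegressor":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["weights"]), d["intercept"], d["feature_space"])


def fit_suvr_regression(
    features: np.ndarray, suvr: np.ndarray, feature_space: str = "latent"
) -> SuvrRegressor:
    """OLS with intercept; rank-deficient designs get the minimum-norm fit."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(suvr, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d features); minimum-norm solution",
            rank, X.shape[1],
        )
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    return SuvrRegressor(beta, intercept, feature_space)


def predict_suvr(features: np.ndarray, model: SuvrRegressor) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != model.weights.shape[0]:
        raise ValueError(
            f"feature length {X.shape[-1]} != regressor dim {model.weights.shape[0]}"
        )
    return X @ model.weights + model.intercept


@dataclasses.dataclass
class BootstrapReport:
    rmse: np.ndarray
    mae: np.ndarray
    auroc: np.ndarray  # NaN where a split had one class
    n_splits: int
    test_fraction: float
    positivity_threshold: float
    n_auroc_missing: int = 0

    def _summary(self, x):
        x = x[np.isfinite(x)]
        return {
            "mean": float(np.mean(x)),
            "ci_low": float(np.percentile(x, 2.5)),
            "ci_high": float(np.percentile(x, 97.5)),
        }

    def summary(self) -> dict:
        return {
            "rmse": self._summary(self.rmse),
            "mae": self._summary(self.mae),
            "auroc": self._summary(self.auroc) if np.isfinite(self.auroc).any() else None,
            "n_splits": self.n_splits,
            "test_fraction": self.test_fraction,
            "positivity_threshold": self.positivity_threshold,
            "n_auroc_missing": self.n_auroc_missing,
        }

    def to_json(self, path: str | Path):
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)

    def __str__(self):
        s = self.summary()
        lines = [f"bootstrap over {self.n_splits} subject-level splits "
                 f"(test fraction {self.test_fraction})"]
        for m in ("rmse", "mae", "auroc"):
            v = s[m]
            if v is None:
                lines.append(f"  {m.upper()}: undefined (single-class splits)")
            else:
                lines.append(
                    f"  {m.upper()}: {v['mean']:.4f} ({v['ci_low']:.4f}, {v['ci_high']:.4f})"
                )
        return "\n".join(lines)


def bootstrap_evaluate(
    features: np.ndarray,
    suvr: np.ndarray,
    subjects: np.ndarray,
    n_splits: int = 1000,
    test_fraction: float = 0.35,
    positivity_threshold: float = NEGATIVE_SUVR,
    seed: int = 0,
) -> BootstrapReport:
    """Random subject-level train/test splits of the SUVR regression.

    For each split an OLS regressor is fitted on the training scans and
    evaluated on the held-out scans: RMSE and MAE of predicted SUVR, and
    AUROC of predicted SUVR as a score for observed SUVR >= threshold.
    Splits where the test set has a single positivity class have no AUROC;
    they are excluded from the AUROC aggregate and counted.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    X = np.asarray(features, dtype=float)
    y = np.asarray(suvr, dtype=float)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    n_test = max(1, int(round(test_fraction * uniq.size)))
    if n_test >= uniq.size:
        raise ValueError("test_fraction leaves no training subjects")
    rng = np.random.default_rng(seed)
    rmse = np.empty(n_splits)
    mae = np.empty(n_splits)
    auroc = np.full(n_splits, np.nan)
    for s in range(n_splits):
        test_subj = rng.choice(uniq, size=n_test, replace=False)
        te = np.isin(subjects, test_subj)
        tr = ~te
        reg = fit_suvr_regression(X[tr], y[tr])
        pred = predict_suvr(X[te], reg)
        err = pred - y[te]
        rmse[s] = np.sqrt(np.mean(err**2))
        mae[s] = np.mean(np.abs(err))
        labels = y[te] >= positivity_threshold
        if labels.any() and not labels.all():
            auroc[s] = roc_auc_score(labels, pred)
    n_missing = int(np.isnan(auroc).sum())
    if n_missing:
        logger.info("%d of %d splits had a single class; AUROC skipped there",
                    n_missing, n_splits)
    return BootstrapReport(
        rmse, mae, auroc, n_splits, test_fraction, positivity_threshold, n_missing
    )


def elbow_curve(
    latents: np.ndarray,
    suvr: np.ndarray,
    subjects: np.ndarray,
    k_values=(1, 2, 3, 5, 8, 10),
    n_splits: int = 100,
    test_fraction: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """SUVR prediction error versus number of principal components.

    Reuses `bootstrap_evaluate` on PCA-projected features for each K.
    """
    latents = np.asarray(latents, dtype=float)
    L = latents.shape[1]
    rows = []
    for k in k_values:
        if k > L:
            raise ValueError(f"K={k} exceeds latent dimension {L}")
        pca = fit_pca(latents, k)
        scores = project(latents, pca)
        rep = bootstrap_evaluate(
            scores, suvr, subjects, n_splits=n_splits,
            test_fraction=test_fraction, seed=seed,
        )
        s = rep.summary()["rmse"]
        rows.append(
            {"K": k, "rmse_mean": s["mean"], "rmse_ci_low": s["ci_low"],
             "rmse_ci_high": s["ci_high"]}
        )
    return pd.DataFrame(rows)


def plot_elbow(curve: pd.DataFrame, path: str | Path):
    """Write the elbow curve (mean RMSE with 95% CI band) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["K"], curve["rmse_mean"], "o-", color="tab:blue")
    ax.fill_between(
        curve["K"], curve["rmse_ci_low"], curve["rmse_ci_high"],
        alpha=0.25, color="tab:blue",
    )
    ax.set_xlabel("number of principal components")
    ax.set_ylabel("SUVR prediction RMSE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
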