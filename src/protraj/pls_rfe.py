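"""PLS regression with recursive feature elimination over grey-matter voxels.

Builds a sparse voxelwise biomarker ("PLS-derived grey matter score") by
regressing a continuous response (a memory composite) on voxelwise
grey-matter density, then iteratively discarding voxels with weak total
linear coefficients under nested cross-validation with early stopping.
The product is a voxel weight map; scoring a new subject is the centered
weighted linear sum of their density over the retained voxels, so higher
scores mean higher grey-matter density (less atrophy).

Densities share a common unit-free [0,1] scale, so predictors are
mean-centered but not variance-scaled; the response is centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "VoxelMatrix",
    "PLSModel",
    "VoxelWeightMap",
    "pls_fit",
    "pls_predict",
    "variance_explained",
    "rfe_loop",
    "gm_score",
    "roi_mean_score",
    "PLSRFE",
    "PLSRFEResults",
    "RFEEliminationError",
]


class RFEEliminationError(RuntimeError):
    """Feature elimination emptied the voxel set; carries the history so far."""

    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


@dataclass
class VoxelMatrix:
    """Dense subjects x voxels grey-matter density with a voxel-index map."""

    values: np.ndarray        # (n_subjects, n_voxels)
    voxel_index: np.ndarray   # (n_voxels, 3) 0-based (i, j, k)
    grid_shape: tuple[int, int, int]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.values.ndim != 2 or self.voxel_index.shape != (self.values.shape[1], 3):
            raise ValueError("values must be n_subjects x n_voxels with one (i,j,k) per column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if np.any(self.voxel_index < 0) or np.any(self.voxel_index >= np.array(self.grid_shape)):
            raise ValueError("voxel indices fall outside the grid")
        lin = self.linear_index()
        if len(np.unique(lin)) != len(lin):
            raise ValueError("duplicate voxel indices")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def linear_index(self) -> np.ndarray:
        return np.ravel_multi_index(self.voxel_index.T, self.grid_shape)


@dataclass
class PLSModel:
    """Mean-centered PLS regression of a scalar response on voxel densities."""

    pls: PLSRegression
    n_components: int

    @property
    def x_mean_(self) -> np.ndarray:
        return self.pls._x_mean

    @property
    def y_mean_(self) -> float:
        return float(np.ravel(self.pls._y_mean)[0])

    @property
    def coef_(self) -> np.ndarray:
        """Total linear coefficients (response units per density unit)."""
        return np.ravel(self.pls.coef_)

    @property
    def x_scores_(self) -> np.ndarray:
        return self.pls.x_scores_

    @property
    def x_weights_(self) -> np.ndarray:
        return self.pls.x_weights_


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int = 1) -> PLSModel:
    """Fit PLS regression (NIPALS deflation, centering only, no scaling)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise ValueError("y must be 1-d with one value per subject")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if X.shape[0] < n_components + 2:
        raise ValueError("need at least n_components + 2 subjects")
    if np.std(y) == 0.0:
        raise ValueError("response has zero variance")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return PLSModel(pls=pls, n_components=n_components)


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.x_mean_.size:
        raise ValueError(
            f"column count {X_new.shape[1]} does not match training ({model.x_mean_.size})")
    return np.ravel(model.pls.predict(X_new))


def variance_explained(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("pred and obs must be equal-length vectors of size >= 3")
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        raise ValueError("zero variance in pred or obs")
    r, _ = stats.pearsonr(pred, obs)
    return float(r ** 2)


@dataclass
class VoxelWeightMap:
    """Sparse voxel -> weight mapping defining the grey-matter score.

    ``weights`` are mean total linear coefficients across the outer folds
    that retained the voxel; ``zstats`` are across-fold z-statistics of the
    weights (reporting only); ``centers`` are training-sample mean densities
    of the retained voxels, so scores are centered at the training cohort.
    """

    voxel_index: np.ndarray   # (m, 3) retained (i, j, k)
    weights: np.ndarray       # (m,)
    grid_shape: tuple[int, int, int]
    centers: np.ndarray       # (m,) training mean density per retained voxel
    zstats: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_retained(self) -> int:
        return len(self.weights)

    def linear_index(self) -> np.ndarray:
        return np.ravel_multi_index(self.voxel_index.T, self.grid_shape)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.voxel_index, columns=["i", "j", "k"])
        df["weight"] = self.weights
        df["center"] = self.centers
        df["zstat"] = self.zstats if self.zstats is not None else np.nan
        return df

    def to_volume(self) -> np.ndarray:
        """Dense weight volume with zeros at eliminated voxels."""
        vol = np.zeros(self.grid_shape)
        vol[tuple(self.voxel_index.T)] = self.weights
        return vol


def _signed_r2(pred, obs):
    """Signed r-squared so anticorrelated predictions do not look like fit."""
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return 0.0
    r, _ = stats.pearsonr(pred, obs)
    return float(np.sign(r) * r ** 2)


def _inner_cv_r2(X, y, n_components, inner_folds, seed):
    """Mean held-out r-squared across inner folds (nan-safe on degenerate folds)."""
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    r2s = []
    for tr, te in kf.split(X):
        m = pls_fit(X[tr], y[tr], n_components=min(n_components, len(tr) - 2))
        r2s.append(_signed_r2(pls_predict(m, X[te]), y[te]))
    return float(np.mean(r2s))


def _elimination_schedule(p: int, drop_fraction: float, min_voxels: int) -> list[int]:
    """Deterministic voxel counts per elimination iteration, starting at p."""
    sizes = [p]
    while sizes[-1] > min_voxels:
        nxt = sizes[-1] - max(1, int(np.floor(drop_fraction * sizes[-1])))
        if nxt <= 0:
            break
        sizes.append(max(nxt, min_voxels))
    return sizes


def _eliminate_to(Xtr, ytr, n_components, schedule, n_iters):
    """Run ``n_iters`` elimination steps; returns the active column subset."""
    active = np.arange(Xtr.shape[1])
    for t in range(n_iters):
        model = pls_fit(Xtr[:, active], ytr,
                        n_components=min(n_components, len(active) - 2))
        n_drop = len(active) - schedule[t + 1]
        keep = np.argsort(np.abs(model.coef_))[n_drop:]
        active = np.sort(active[keep])
    return active


def rfe_loop(X: VoxelMatrix, y: np.ndarray, folds: int = 5,
             drop_fraction: float = 0.10, patience: int = 3, seed: int = 0,
             n_components_grid: Sequence[int] = (1, 2, 3),
             inner_folds: int = 3, min_voxels: int = 5) -> VoxelWeightMap:
    """Nested-CV recursive feature elimination over voxels.

    Within each of ``folds`` outer folds, a fresh elimination path
    (repeatedly dropping the ``drop_fraction`` of active voxels with the
    smallest absolute total linear coefficient) is run inside each inner
    fold for every candidate component count, scoring every iteration on
    that fold's held-out subjects.  Re-running elimination inside the inner
    folds keeps the validation r-squared free of feature-selection bias.
    Paths advance in lockstep and stop early once their mean validation
    r-squared has not improved for ``patience`` iterations; the component
    count and stopping iteration with the best inner validation score are
    then replayed on the full outer-training set to give the fold's
    retained voxels and weights.  The final map keeps voxels retained by a
    majority of outer folds, with across-fold mean weights and
    z-statistics.
    """
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in (0, 1)")
    if len(y) != X.n_subjects:
        raise ValueError("response length must equal number of subjects")

    rng = np.random.default_rng(seed)
    outer = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2 ** 31)))
    p = X.n_voxels
    retain_counts = np.zeros(p, dtype=int)
    weight_sums = np.zeros(p)
    weight_sq_sums = np.zeros(p)
    fold_records = []

    schedule = _elimination_schedule(p, drop_fraction, min_voxels)
    if len(schedule) < 2:
        raise RFEEliminationError(
            f"drop_fraction={drop_fraction} empties the voxel set in one step "
            f"from {p} voxels", [])

    for fold_id, (tr, te) in enumerate(outer.split(X.values)):
        Xtr, ytr = X.values[tr], y[tr]
        inner_seed = int(rng.integers(2 ** 31))

        # lockstep elimination paths inside the inner folds, one family of
        # paths per candidate component count; every iteration is scored on
        # subjects unseen by that path's selection, and the component count
        # and stopping iteration are chosen jointly from the same curves
        inner = KFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed)
        splits = list(inner.split(Xtr))
        best_r2, best_iter, n_components = -np.inf, 0, n_components_grid[0]
        history = []
        for nc in n_components_grid:
            actives = [np.arange(p) for _ in splits]
            nc_best, nc_iter, stall = -np.inf, 0, 0
            curve = []
            for t, size in enumerate(schedule):
                fold_r2 = []
                coefs = []
                for (itr, ite), act in zip(splits, actives):
                    model = pls_fit(Xtr[itr][:, act], ytr[itr],
                                    n_components=min(nc, len(itr) - 2, len(act)))
                    fold_r2.append(_signed_r2(
                        pls_predict(model, Xtr[ite][:, act]), ytr[ite]))
                    coefs.append(model.coef_)
                r2 = float(np.mean(fold_r2))
                curve.append({"n_voxels": size, "n_components": nc,
                              "inner_cv_r2": r2})
                if r2 > nc_best:
                    nc_best, nc_iter, stall = r2, t, 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
                if t + 1 >= len(schedule):
                    break
                n_next = schedule[t + 1]
                actives = [np.sort(act[np.argsort(np.abs(c))[len(act) - n_next:]])
                           for act, c in zip(actives, coefs)]
            history.extend(curve)
            if nc_best > best_r2:
                best_r2, best_iter, n_components = nc_best, nc_iter, nc

        best_active = _eliminate_to(Xtr, ytr, n_components, schedule, best_iter)
        final_model = pls_fit(Xtr[:, best_active], ytr,
                              n_components=min(n_components, len(best_active) - 2))
        w = final_model.coef_
        retain_counts[best_active] += 1
        weight_sums[best_active] += w
        weight_sq_sums[best_active] += w ** 2
        fold_records.append({
            "fold": fold_id,
            "n_components": n_components,
            "n_retained": len(best_active),
            "inner_cv_r2": best_r2,
            "test_idx": te.tolist(),
            # this fold's own model, for leakage-free held-out evaluation
            "retained_cols": best_active.tolist(),
            "fold_weights": w.tolist(),
            "fold_centers": Xtr[:, best_active].mean(axis=0).tolist(),
            "fold_y_mean": float(ytr.mean()),
            "history": history,
        })

    majority = retain_counts > folds / 2
    if not np.any(majority):
        raise RFEEliminationError(
            "no voxel was retained by a majority of folds",
            [rec["history"] for rec in fold_records])
    kept = np.flatnonzero(majority)
    counts = retain_counts[kept].astype(float)
    mean_w = weight_sums[kept] / counts
    var_w = weight_sq_sums[kept] / counts - mean_w ** 2
    sd_w = np.sqrt(np.clip(var_w, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_w > 0, mean_w / (sd_w / np.sqrt(counts)), np.nan)
    centers = X.values[:, kept].mean(axis=0)
    return VoxelWeightMap(
        voxel_index=X.voxel_index[kept],
        weights=mean_w,
        grid_shape=X.grid_shape,
        centers=centers,
        zstats=z,
        provenance={"folds": fold_records, "seed": seed,
                    "drop_fraction": drop_fraction, "patience": patience},
        affine=X.affine,
    )


def gm_score(weight_map: VoxelWeightMap, X_new: VoxelMatrix) -> np.ndarray:
    """Centered weighted linear sum of retained voxel densities per subject."""
    lin_new = X_new.linear_index()
    pos = {v: i for i, v in enumerate(lin_new)}
    cols = []
    for v, ijk in zip(weight_map.linear_index(), weight_map.voxel_index):
        if v not in pos:
            raise KeyError(f"voxel index {tuple(ijk)} missing from input matrix")
        cols.append(pos[v])
    cols = np.asarray(cols, dtype=int)
    return (X_new.values[:, cols] - weight_map.centers) @ weight_map.weights


def roi_mean_score(mask: np.ndarray, X: VoxelMatrix) -> np.ndarray:
    """Mean density over an a-priori region of interest, per subject.

    ``mask`` is a set of (i, j, k) voxel coordinates; every masked voxel
    must be present in the matrix.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("empty mask")
    if mask.ndim != 2 or mask.shape[1] != 3:
        raise ValueError("mask must be an array of (i, j, k) coordinates")
    lin_mask = np.ravel_multi_index(mask.T, X.grid_shape)
    pos = {v: i for i, v in enumerate(X.linear_index())}
    try:
        cols = np.asarray([pos[v] for v in lin_mask], dtype=int)
    except KeyError as e:
        raise KeyError(f"mask voxel with linear index {e.args[0]} missing from matrix")
    return X.values[:, cols].mean(axis=1)


# ---------------------------------------------------------------------------
# model/results wrappers


class PLSRFE:
    """PLS-RFE model bound to a voxel matrix and a continuous response."""

    def __init__(self, X: VoxelMatrix, y: np.ndarray):
        self.X = X
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != X.n_subjects:
            raise ValueError("response length must equal number of subjects")

    def fit(self, folds: int = 5, drop_fraction: float = 0.10, patience: int = 3,
            seed: int = 0, **kwargs) -> "PLSRFEResults":
        wmap = rfe_loop(self.X, self.y, folds=folds, drop_fraction=drop_fraction,
                        patience=patience, seed=seed, **kwargs)
        return PLSRFEResults(weight_map=wmap, model=self)


@dataclass
class PLSRFEResults:
    weight_map: VoxelWeightMap
    model: PLSRFE

    def score(self, X_new: VoxelMatrix) -> np.ndarray:
        return gm_score(self.weight_map, X_new)

    def held_out_r2(self) -> float:
        """Variance in the response explained on the outer test folds.

        Each fold's subjects are scored with that fold's own voxel set and
        weights, so the estimate is free of selection leakage.
        """
        r2s = []
        for rec in self.weight_map.provenance["folds"]:
            te = np.asarray(rec["test_idx"], dtype=int)
            cols = np.asarray(rec["retained_cols"], dtype=int)
            w = np.asarray(rec["fold_weights"])
            centers = np.asarray(rec["fold_centers"])
            pred = (self.model.X.values[np.ix_(te, cols)] - centers) @ w
            r2s.append(variance_explained(pred, self.model.y[te]))
        return float(np.mean(r2s))

    def summary(self) -> str:
        wm = self.weight_map
        lines = ["PLS-RFE results", "=" * 45]
        lines.append(f"input voxels:    {self.model.X.n_voxels}")
        lines.append(f"retained voxels: {wm.n_retained}")
        lines.append(f"outer folds:     {len(wm.provenance['folds'])}")
        comps = [rec["n_components"] for rec in wm.provenance["folds"]]
        lines.append(f"components/fold: {comps}")
        lines.append(f"held-out r2:     {self.held_out_r2():.4f}")
        lines.append(f"weight range:    [{wm.weights.min():.4g}, {wm.weights.max():.4g}]")
        return "\n".join(lines)
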