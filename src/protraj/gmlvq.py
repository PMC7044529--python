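"""Generalised Matrix Learning Vector Quantization with a scalar-projection score.

GMLVQ is a prototype-based classifier that learns, alongside one (or two)
prototype vectors per class, a full positive-semidefinite metric tensor
``lambda = omega.T @ omega`` defining the distance

    d(x, w) = (x - w)^T lambda (x - w).

Training performs stochastic steepest descent on the Sato-Yamada cost
``sum_i mu_i`` with ``mu_i = (d_J - d_K) / (d_J + d_K)``, where ``d_J`` is
the distance to the closest prototype of the sample's own class and ``d_K``
the distance to the closest prototype of the other class.  After every
update ``omega`` is renormalised so that ``trace(lambda) = 1``; the diagonal
of ``lambda`` is then directly interpretable as a per-feature relevance
profile, and the off-diagonal terms as signed pairwise interactions.

For the two-prototype (linear) model the classifier additionally yields a
continuous prognostic score: the lambda-weighted projection of a sample onto
the axis running from the stable-class prototype (score 0) through the
decision boundary (score 0.5) to the progressive-class prototype (score 1).
Scores below 0 or above 1 are meaningful: they place a subject beyond the
prototypes along the learned axis of disease progression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "STABLE",
    "PROGRESSIVE",
    "Standardizer",
    "standardize",
    "metric_distance",
    "glvq_cost",
    "glvq_cost_gradient",
    "GMLVQ",
    "GMLVQResults",
    "GMLVQClassifier",
    "DegenerateSampleError",
    "TrainingDivergedError",
]

STABLE = "stable"
PROGRESSIVE = "progressive"


class DegenerateSampleError(ValueError):
    """A sample coincides with prototypes of both classes (d_J + d_K = 0)."""


class TrainingDivergedError(RuntimeError):
    """Training cost became non-finite; carries the offending epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training cost at epoch {epoch}")
        self.epoch = epoch


# ---------------------------------------------------------------------------
# feature standardization


class Standardizer:
    """Per-feature center/scale estimated on training data only.

    Parameters are stored so held-out samples are transformed identically.
    A zero-variance feature is rejected by name: metric learning cannot
    meaningfully weight a constant column.
    """

    def __init__(self, mean: np.ndarray, scale: np.ndarray, feature_names: list[str]):
        self.mean_ = np.asarray(mean, dtype=float)
        self.scale_ = np.asarray(scale, dtype=float)
        self.feature_names = list(feature_names)

    @classmethod
    def fit(cls, X: np.ndarray, feature_names: Sequence[str] | None = None) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardization needs a 2-d matrix with >= 2 rows")
        names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(X.shape[1])]
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        for j, s in enumerate(scale):
            if s == 0.0:
                raise ValueError(f"feature {names[j]!r} has zero variance")
        return cls(mean, scale, names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(np.array(d["mean"]), np.array(d["scale"]), d["feature_names"])


def standardize(train: np.ndarray, apply_to: np.ndarray,
                feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Z-score ``apply_to`` with center/scale estimated from ``train``."""
    return Standardizer.fit(train, feature_names).transform(apply_to)


# ---------------------------------------------------------------------------
# distances and cost


def metric_distance(x: np.ndarray, w: np.ndarray, lam: np.ndarray) -> float:
    """Squared distance (x-w)^T lambda (x-w) under the metric tensor."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if x.shape != w.shape or lam.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, w {w.shape}, lambda {lam.shape}")
    diff = x - w
    return float(diff @ lam @ diff)


def _winner_distances(x, prototypes, proto_labels, label, lam):
    """Distances and indices of the closest same-class and other-class prototypes."""
    diffs = prototypes - x
    d = np.einsum("pi,ij,pj->p", diffs, lam, diffs)
    same = proto_labels == label
    j = int(np.flatnonzero(same)[np.argmin(d[same])])
    k = int(np.flatnonzero(~same)[np.argmin(d[~same])])
    return d[j], d[k], j, k


def glvq_cost(X: np.ndarray, y: np.ndarray, prototypes: np.ndarray,
              proto_labels: np.ndarray, lam: np.ndarray) -> float:
    """Sato-Yamada cost: sum over samples of (d_J - d_K)/(d_J + d_K).

    Each term lies in [-1, 1]; lower is better (negative terms are
    correctly classified samples).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    proto_labels = np.asarray(proto_labels)
    total = 0.0
    for i in range(X.shape[0]):
        dj, dk, _, _ = _winner_distances(X[i], prototypes, proto_labels, y[i], lam)
        s = dj + dk
        if s == 0.0:
            raise DegenerateSampleError(
                f"sample {i} coincides with prototypes of both classes")
        total += (dj - dk) / s
    return float(total)


def glvq_cost_gradient(X, y, prototypes, proto_labels, omega):
    """Full-batch analytic gradient of ``glvq_cost`` w.r.t. prototypes and omega.

    Returns ``(grad_prototypes, grad_omega)`` for the un-normalised
    parameterisation ``lambda = omega.T @ omega`` (no trace renormalisation),
    so that it is directly comparable with finite differences.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    prototypes = np.asarray(prototypes, dtype=float)
    proto_labels = np.asarray(proto_labels)
    omega = np.asarray(omega, dtype=float)
    lam = omega.T @ omega
    gP = np.zeros_like(prototypes)
    gO = np.zeros_like(omega)
    for i in range(X.shape[0]):
        dj, dk, j, k = _winner_distances(X[i], prototypes, proto_labels, y[i], lam)
        s = dj + dk
        if s == 0.0:
            raise DegenerateSampleError(f"sample {i} coincides with both prototypes")
        gj = 2.0 * dk / s ** 2      # d mu / d d_J
        gk = -2.0 * dj / s ** 2     # d mu / d d_K
        ej = X[i] - prototypes[j]
        ek = X[i] - prototypes[k]
        gP[j] += gj * (-2.0 * lam @ ej)
        gP[k] += gk * (-2.0 * lam @ ek)
        gO += 2.0 * omega @ (gj * np.outer(ej, ej) + gk * np.outer(ek, ek))
    return gP, gO


# ---------------------------------------------------------------------------
# model / results


@dataclass
class GMLVQResults:
    """Fitted GMLVQ model: prototypes, metric tensor, and derived quantities."""

    prototypes: np.ndarray              # (n_prototypes, n_features), standardized space
    proto_labels: np.ndarray            # class label per prototype
    omega: np.ndarray                   # (n_features, n_features)
    standardizer: Standardizer
    training_log: list[float]           # per-epoch cost
    hyperparams: dict
    seed: int
    progressive_label: str = PROGRESSIVE
    stable_label: str = STABLE

    @property
    def lambda_(self) -> np.ndarray:
        return self.omega.T @ self.omega

    @property
    def feature_names(self) -> list[str]:
        return self.standardizer.feature_names

    # -- classification ----------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Nearest-prototype labels; boundary ties resolve to the stable class."""
        Z = self.standardizer.transform(np.atleast_2d(np.asarray(X, dtype=float)))
        lam = self.lambda_
        out = []
        for x in Z:
            diffs = self.prototypes - x
            d = np.einsum("pi,ij,pj->p", diffs, lam, diffs)
            d_stable = d[self.proto_labels == self.stable_label].min()
            d_prog = d[self.proto_labels == self.progressive_label].min()
            out.append(self.stable_label if d_stable <= d_prog else self.progressive_label)
        return np.asarray(out)

    def relevance_profile(self) -> tuple[pd.Series, pd.DataFrame]:
        """Diagonal relevances (sum to 1) and signed off-diagonal interactions."""
        lam = self.lambda_
        names = self.feature_names
        diag = pd.Series(np.diag(lam), index=names, name="relevance")
        inter = pd.DataFrame(lam - np.diag(np.diag(lam)), index=names, columns=names)
        return diag, inter

    # -- scalar projection -------------------------------------------------
    def _prototype_pair(self):
        if len(self.prototypes) != 2:
            raise ValueError(
                "scalar projection is defined for the linear model only "
                "(exactly one prototype per class)")
        ws = self.prototypes[self.proto_labels == self.stable_label][0]
        wp = self.prototypes[self.proto_labels == self.progressive_label][0]
        return ws, wp

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scalar-projection prognostic score per subject.

        s(x) = (x - w_s)^T lambda (w_p - w_s) / (w_p - w_s)^T lambda (w_p - w_s);
        0 at the stable prototype, 1 at the progressive prototype, 0.5 on the
        decision boundary; unbounded beyond the prototypes.
        """
        ws, wp = self._prototype_pair()
        Z = self.standardizer.transform(np.atleast_2d(np.asarray(X, dtype=float)))
        lam = self.lambda_
        axis = lam @ (wp - ws)
        denom = float((wp - ws) @ axis)
        if denom == 0.0:
            raise ValueError("degenerate prototypes: w_s and w_p coincide under lambda")
        return (Z - ws) @ axis / denom

    def project_standardized(self, Z: np.ndarray) -> np.ndarray:
        """Scalar projection of points already in the standardized space."""
        ws, wp = self._prototype_pair()
        lam = self.lambda_
        axis = lam @ (wp - ws)
        denom = float((wp - ws) @ axis)
        if denom == 0.0:
            raise ValueError("degenerate prototypes: w_s and w_p coincide under lambda")
        return np.atleast_2d(np.asarray(Z, dtype=float) - ws) @ axis / denom

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        diag, inter = self.relevance_profile()
        lines = ["GMLVQ results", "=" * 45]
        lines.append(f"features:             {', '.join(self.feature_names)}")
        lines.append(f"prototypes per class: {len(self.prototypes) // 2}")
        lines.append(f"epochs run:           {len(self.training_log)}")
        lines.append(f"final cost:           {self.training_log[-1]:.6f}")
        lines.append(f"seed:                 {self.seed}")
        lines.append("-" * 45)
        lines.append("feature relevances (diagonal of lambda):")
        for name, v in diag.items():
            lines.append(f"  {name:<20s} {v:8.4f}")
        lines.append("pairwise interactions (off-diagonal of lambda):")
        names = self.feature_names
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                lines.append(f"  {names[a]} x {names[b]:<14s} {inter.iloc[a, b]:8.4f}")
        return "\n".join(lines)

    def plot_relevances(self, ax=None):
        """Heatmap of the metric tensor lambda (relevances and interactions)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lam = self.lambda_
        im = ax.imshow(lam, cmap="RdBu_r", vmin=-np.abs(lam).max(), vmax=np.abs(lam).max())
        ax.set_xticks(range(len(self.feature_names)), self.feature_names, rotation=45)
        ax.set_yticks(range(len(self.feature_names)), self.feature_names)
        ax.figure.colorbar(im, ax=ax, label="lambda")
        ax.set_title("metric tensor")
        return ax

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "prototypes": self.prototypes.tolist(),
            "proto_labels": self.proto_labels.tolist(),
            "omega": self.omega.tolist(),
            "standardizer": self.standardizer.to_dict(),
            "training_log": list(self.training_log),
            "hyperparams": dict(self.hyperparams),
            "seed": self.seed,
            "progressive_label": self.progressive_label,
            "stable_label": self.stable_label,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GMLVQResults":
        return cls(
            prototypes=np.array(d["prototypes"], dtype=float),
            proto_labels=np.array(d["proto_labels"]),
            omega=np.array(d["omega"], dtype=float),
            standardizer=Standardizer.from_dict(d["standardizer"]),
            training_log=list(d["training_log"]),
            hyperparams=dict(d["hyperparams"]),
            seed=int(d["seed"]),
            progressive_label=d["progressive_label"],
            stable_label=d["stable_label"],
        )

    @classmethod
    def from_json(cls, path) -> "GMLVQResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class GMLVQ:
    """GMLVQ model specification bound to a training sample.

    Parameters
    ----------
    X : array-like, (n_subjects, n_features)
        Feature matrix (raw scale; z-scored internally unless
        ``standardize=False``).
    y : array-like of class labels
        Binary labels; ``progressive_label`` marks the positive
        (progressing) class, every other value the stable class.
    feature_names : optional list of column names.
    prototypes_per_class : 1 (linear decision boundary) or 2.
    """

    def __init__(self, X, y, feature_names=None, prototypes_per_class: int = 1,
                 progressive_label: str = PROGRESSIVE, standardize: bool = True):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-d with at least 2 features")
        if len(y) != X.shape[0]:
            raise ValueError("label vector length must equal n_subjects")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        if prototypes_per_class not in (1, 2):
            raise ValueError("prototypes_per_class must be 1 or 2")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {classes}")
        if progressive_label not in classes:
            raise ValueError(f"progressive label {progressive_label!r} absent from y")
        self.progressive_label = progressive_label
        self.stable_label = str([c for c in classes if c != progressive_label][0])
        self.prototypes_per_class = prototypes_per_class
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"f{j}" for j in range(X.shape[1])])
        if standardize:
            self.standardizer = Standardizer.fit(X, self.feature_names)
        else:
            self.standardizer = Standardizer(
                np.zeros(X.shape[1]), np.ones(X.shape[1]), self.feature_names)
        self.X_ = self.standardizer.transform(X)
        self.y_ = y.astype(str)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features: Sequence[str], label: str,
                       **kwargs) -> "GMLVQ":
        missing = [c for c in list(features) + [label] if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in dataframe: {missing}")
        sub = df.dropna(subset=list(features) + [label])
        return cls(sub[list(features)].to_numpy(float), sub[label].to_numpy(),
                   feature_names=list(features), **kwargs)

    def fit(self, alpha_w: float = 0.05, alpha_omega: float = 0.01,
            max_epochs: int = 300, tol: float = 1e-6, patience: int = 20,
            seed: int = 0, update_callback=None) -> GMLVQResults:
        """Stochastic steepest descent on the GLVQ cost.

        Prototypes start at class-conditional means plus a small seeded
        jitter; omega starts at I/sqrt(D) so trace(lambda)=1.  Omega is
        renormalised to unit Frobenius norm after every update.  Training
        stops after ``max_epochs`` epochs or once the epoch cost has not
        improved by more than ``tol`` for ``patience`` consecutive epochs.
        ``update_callback(prototypes, omega)``, if given, is invoked after
        every per-sample update (intended for diagnostics).
        """
        if alpha_w <= 0 or alpha_omega < 0:
            raise ValueError("learning rates must be positive (alpha_omega may be 0)")
        rng = np.random.default_rng(seed)
        X, y = self.X_, self.y_
        n, D = X.shape

        protos, labels = [], []
        for c in (self.stable_label, self.progressive_label):
            Xc = X[y == c]
            if len(Xc) == 0:
                raise ValueError(f"class {c!r} has no samples")
            mean = Xc.mean(axis=0)
            for _ in range(self.prototypes_per_class):
                protos.append(mean + 0.01 * rng.standard_normal(D))
                labels.append(c)
        prototypes = np.array(protos)
        proto_labels = np.asarray(labels)
        omega = np.eye(D) / np.sqrt(D)

        log: list[float] = []
        best = np.inf
        stall = 0
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            lam = omega.T @ omega
            for i in order:
                dj, dk, j, k = _winner_distances(X[i], prototypes, proto_labels, y[i], lam)
                s = dj + dk
                if s == 0.0:
                    raise DegenerateSampleError(
                        f"sample {i} coincides with prototypes of both classes")
                gj = 2.0 * dk / s ** 2
                gk = -2.0 * dj / s ** 2
                ej = X[i] - prototypes[j]
                ek = X[i] - prototypes[k]
                prototypes[j] += alpha_w * gj * 2.0 * (lam @ ej)
                prototypes[k] += alpha_w * gk * 2.0 * (lam @ ek)
                if alpha_omega > 0.0:
                    omega -= alpha_omega * 2.0 * omega @ (
                        gj * np.outer(ej, ej) + gk * np.outer(ek, ek))
                    omega /= np.linalg.norm(omega)
                    lam = omega.T @ omega
                if update_callback is not None:
                    update_callback(prototypes, omega)
            cost = glvq_cost(X, y, prototypes, proto_labels, omega.T @ omega)
            if not np.isfinite(cost):
                raise TrainingDivergedError(epoch)
            log.append(cost)
            if best - cost > tol:
                best = cost
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break

        return GMLVQResults(
            prototypes=prototypes,
            proto_labels=proto_labels,
            omega=omega,
            standardizer=self.standardizer,
            training_log=log,
            hyperparams={"alpha_w": alpha_w, "alpha_omega": alpha_omega,
                         "max_epochs": max_epochs, "tol": tol, "patience": patience},
            seed=seed,
            progressive_label=self.progressive_label,
            stable_label=self.stable_label,
        )


class GMLVQClassifier(BaseEstimator, ClassifierMixin):
    """Thin scikit-learn-style wrapper so GMLVQ plugs into CV machinery."""

    def __init__(self, alpha_w=0.05, alpha_omega=0.01, prototypes_per_class=1,
                 max_epochs=300, progressive_label=PROGRESSIVE, seed=0):
        self.alpha_w = alpha_w
        self.alpha_omega = alpha_omega
        self.prototypes_per_class = prototypes_per_class
        self.max_epochs = max_epochs
        self.progressive_label = progressive_label
        self.seed = seed

    def fit(self, X, y):
        model = GMLVQ(X, y, prototypes_per_class=self.prototypes_per_class,
                      progressive_label=self.progressive_label)
        self.results_ = model.fit(alpha_w=self.alpha_w, alpha_omega=self.alpha_omega,
                                  max_epochs=self.max_epochs, seed=self.seed)
        self.classes_ = np.unique(np.asarray(y).astype(str))
        return self

    def predict(self, X):
        return self.results_.predict(X)

    def project(self, X):
        return self.results_.project(X)
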