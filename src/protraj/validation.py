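"""Evaluation machinery: cross-validation, resampling, and correlation inference.

Conventions used throughout:

* the progressive class is the positive class; true-positive rate is
  sensitivity over progressive subjects, true-negative rate specificity over
  stable subjects;
* macro-averaged error (MAE) = 100 - (TPR + TNR)/2, in percent;
* Pearson confidence intervals use the Fisher z transform;
* two independent correlations are compared with the Fisher r-to-Z test,
  two dependent correlations sharing an outcome with Steiger's Z (the
  pooled-estimate variant of Steiger 1980);
* rates of cognitive decline are OLS slopes of score against years since
  baseline, requiring at least three visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .gmlvq import GMLVQ, GMLVQResults, PROGRESSIVE, STABLE

__all__ = [
    "ClassificationMetrics",
    "CorrelationResult",
    "RateOfChange",
    "classification_metrics",
    "kfold_cv",
    "CVResult",
    "random_resampling",
    "ResamplingResult",
    "rate_of_change",
    "exclude_outliers",
    "pearson_ci",
    "adjusted_correlation",
    "fisher_r_to_z",
    "steiger_z",
    "positivity_threshold",
    "group_compare",
]


# ---------------------------------------------------------------------------
# classification metrics


@dataclass
class ClassificationMetrics:
    """Percent-scale summary of a binary prognosis (progressive = positive)."""

    accuracy: float
    macro_averaged_error: float
    true_positive_rate: float
    true_negative_rate: float

    def round(self, ndigits: int = 1) -> "ClassificationMetrics":
        """Half-away-from-zero rounding, applied only at the reporting layer."""
        def r(v):
            return float(np.floor(v * 10 ** ndigits + 0.5) / 10 ** ndigits)
        return ClassificationMetrics(r(self.accuracy), r(self.macro_averaged_error),
                                     r(self.true_positive_rate), r(self.true_negative_rate))

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "macro_averaged_error": self.macro_averaged_error,
                "true_positive_rate": self.true_positive_rate,
                "true_negative_rate": self.true_negative_rate}


def classification_metrics(true, predicted,
                           progressive_label: str = PROGRESSIVE) -> ClassificationMetrics:
    true = np.asarray(true).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if true.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    pos = true == progressive_label
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present in the true labels")
    tpr = 100.0 * np.mean(predicted[pos] == progressive_label)
    tnr = 100.0 * np.mean(predicted[~pos] != progressive_label)
    acc = 100.0 * np.mean(predicted == true)
    mae = 100.0 - (tpr + tnr) / 2.0
    return ClassificationMetrics(acc, mae, tpr, tnr)


def metrics_from_rates(tpr: float, tnr: float, n_positive: int,
                       n_negative: int) -> ClassificationMetrics:
    """Metrics implied by class-wise rates and class sizes (pooled accuracy)."""
    acc = (tpr * n_positive + tnr * n_negative) / (n_positive + n_negative)
    return ClassificationMetrics(acc, 100.0 - (tpr + tnr) / 2.0, tpr, tnr)


# ---------------------------------------------------------------------------
# cross-validation with nested tuning


@dataclass
class CVResult:
    mean_metrics: ClassificationMetrics
    fold_metrics: list[ClassificationMetrics]
    chosen_params: list[dict]
    seed: int

    def summary(self) -> str:
        m = self.mean_metrics.round()
        return (f"{len(self.fold_metrics)}-fold CV: accuracy {m.accuracy}%, "
                f"MAE {m.macro_averaged_error}%, TP {m.true_positive_rate}%, "
                f"TN {m.true_negative_rate}%")


def kfold_cv(X, y, model_factory: Callable[..., object], k: int,
             hyperparam_grid: Sequence[dict] | None = None, seed: int = 0,
             inner_k: int = 3,
             progressive_label: str = PROGRESSIVE) -> CVResult:
    """Stratified k-fold CV with per-fold nested hyperparameter selection.

    ``model_factory(**params)`` must return an estimator with sklearn-style
    ``fit(X, y)`` and ``predict(X)``.  Hyperparameters are chosen per outer
    fold by minimising the inner-CV macro-averaged error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if k < 2:
        raise ValueError("k must be >= 2")
    grid = list(hyperparam_grid) if hyperparam_grid else [{}]
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics, chosen = [], []
    for tr, te in outer.split(X, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a fold lacks one of the classes; reduce k or rebalance")
        best_params, best_mae = grid[0], np.inf
        if len(grid) > 1:
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + 1)
            for params in grid:
                maes = []
                for itr, ite in inner.split(X[tr], y[tr]):
                    est = model_factory(**params)
                    est.fit(X[tr][itr], y[tr][itr])
                    m = classification_metrics(y[tr][ite], est.predict(X[tr][ite]),
                                               progressive_label)
                    maes.append(m.macro_averaged_error)
                mean_mae = float(np.mean(maes))
                if mean_mae < best_mae:
                    best_mae, best_params = mean_mae, params
        est = model_factory(**best_params)
        est.fit(X[tr], y[tr])
        fold_metrics.append(classification_metrics(y[te], est.predict(X[te]),
                                                   progressive_label))
        chosen.append(dict(best_params))
    mean = ClassificationMetrics(
        float(np.mean([m.accuracy for m in fold_metrics])),
        float(np.mean([m.macro_averaged_error for m in fold_metrics])),
        float(np.mean([m.true_positive_rate for m in fold_metrics])),
        float(np.mean([m.true_negative_rate for m in fold_metrics])),
    )
    return CVResult(mean, fold_metrics, chosen, seed)


# ---------------------------------------------------------------------------
# random resampling with median-model selection


@dataclass
class ResamplingResult:
    test_correlations: np.ndarray
    median_r: float
    ci95: tuple[float, float]
    median_model: GMLVQResults
    train_size: int
    seed: int

    def summary(self) -> str:
        lo, hi = self.ci95
        return (f"{len(self.test_correlations)} resamples (train n={self.train_size}): "
                f"median test r = {self.median_r:.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")


def random_resampling(X, y, outcome_slopes, n_resamples: int = 1000,
                      train_size: int = 52, seed: int = 0,
                      feature_names: Sequence[str] | None = None,
                      progressive_label: str = PROGRESSIVE,
                      **fit_kwargs) -> ResamplingResult:
    """Repeatedly train GMLVQ on stratified subsamples; correlate held-out
    scalar projections with outcome slopes.

    Returns the distribution of test correlations, its median with a
    percentile 95% CI, and the fitted model whose test correlation is
    closest to the median (kept for out-of-sample reuse).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    outcome_slopes = np.asarray(outcome_slopes, dtype=float)
    n = len(y)
    if train_size >= n:
        raise ValueError("train_size must be smaller than the sample")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_per_class = {c: max(2, int(round(train_size * cnt / n)))
                   for c, cnt in zip(classes, counts)}
    rs, models = [], []
    for _ in range(n_resamples):
        train_idx = []
        for c in classes:
            members = np.flatnonzero(y == c)
            train_idx.extend(rng.choice(members, size=n_per_class[c], replace=False))
        train_idx = np.asarray(sorted(train_idx))
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        model = GMLVQ(X[train_idx], y[train_idx], feature_names=feature_names,
                      progressive_label=progressive_label)
        res = model.fit(seed=int(rng.integers(2 ** 31)), **fit_kwargs)
        proj = res.project(X[test_idx])
        r, _ = stats.pearsonr(proj, outcome_slopes[test_idx])
        rs.append(float(r))
        models.append(res)
    rs = np.asarray(rs)
    median = float(np.median(rs))
    if n_resamples == 1:
        ci = (rs[0], rs[0])
    else:
        ci = tuple(np.percentile(rs, [2.5, 97.5]).tolist())
    median_model = models[int(np.argmin(np.abs(rs - median)))]
    return ResamplingResult(rs, median, ci, median_model, train_size, seed)


# ---------------------------------------------------------------------------
# longitudinal slopes, outliers, positivity


@dataclass
class RateOfChange:
    slope: float          # score units per year
    intercept: float
    n_timepoints: int


def rate_of_change(times, scores) -> RateOfChange:
    """OLS slope of a longitudinal score against years since baseline."""
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if times.size != scores.size or times.size < 3:
        raise ValueError("need at least 3 timepoints")
    if len(np.unique(times)) < 2:
        raise ValueError("times must not all coincide")
    slope, intercept = np.polyfit(times, scores, 1)
    return RateOfChange(float(slope), float(intercept), int(times.size))


def exclude_outliers(projections, labels,
                     progressive_label: str = PROGRESSIVE) -> tuple[np.ndarray, pd.DataFrame]:
    """Two-standard-deviation outlier rule on scalar projections.

    Excludes subjects whose projection exceeds the stable-class mean by more
    than 2 stable-class SDs, or falls below the progressive-class mean by
    more than 2 progressive-class SDs.  Thresholds are computed once from
    the full input.  Returns (retained indices, exclusion log).
    """
    projections = np.asarray(projections, dtype=float)
    labels = np.asarray(labels).astype(str)
    pos = labels == progressive_label
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("each class needs >= 2 members to estimate an SD")
    hi = projections[~pos].mean() + 2.0 * projections[~pos].std(ddof=0)
    lo = projections[pos].mean() - 2.0 * projections[pos].std(ddof=0)
    out = (projections > hi) | (projections < lo)
    log = pd.DataFrame({
        "index": np.flatnonzero(out),
        "projection": projections[out],
        "label": labels[out],
        "upper_threshold": hi,
        "lower_threshold": lo,
    })
    return np.flatnonzero(~out), log


def positivity_threshold(reference_values, values) -> tuple[float, np.ndarray]:
    """Biomarker positivity against a reference group's 90th percentile.

    The threshold is the linearly interpolated 90th percentile of the
    reference values (e.g. amyloid-negative, cognitively normal subjects);
    a subject is positive only if strictly above it.
    """
    reference_values = np.asarray(reference_values, dtype=float)
    values = np.asarray(values, dtype=float)
    if reference_values.size == 0:
        raise ValueError("empty reference group")
    if reference_values.size < 10:
        raise ValueError("reference group must have >= 10 subjects")
    thr = float(np.percentile(reference_values, 90))
    return thr, values > thr


# ---------------------------------------------------------------------------
# correlation inference


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci95: tuple[float, float]
    p: float
    adjusted: bool = False

    def summary(self) -> str:
        df = self.n - 2 - (1 if self.adjusted else 0)
        lo, hi = self.ci95
        return f"r({df}) = {self.r:.2f} (95% CI: [{lo:.2f} {hi:.2f}]), P = {self.p:.2g}"


def _fisher_ci(r: float, n: int, df_loss: int = 0) -> tuple[float, float]:
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3 - df_loss)
    q = stats.norm.ppf(0.975)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def pearson_ci(x, y) -> CorrelationResult:
    """Pearson correlation with a Fisher-transform 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors with n >= 4")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), int(x.size), _fisher_ci(r, x.size), float(p))


def adjusted_correlation(x, y, covariate) -> CorrelationResult:
    """Partial Pearson correlation controlling for one covariate.

    Both variables are residualised on the covariate (with intercept) and
    the residuals correlated; one degree of freedom is lost.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.size == y.size == c.size) or x.size < 5:
        raise ValueError("need three paired vectors with n >= 5")
    design = np.column_stack([np.ones_like(c), c])

    def resid(v):
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = resid(x), resid(y)
    n = x.size
    # a variable fully explained by the covariate leaves nothing to
    # correlate: the partial correlation is 0 by convention
    tol_x = 1e-12 * max(np.var(x), 1.0)
    tol_y = 1e-12 * max(np.var(y), 1.0)
    if np.var(rx) <= tol_x or np.var(ry) <= tol_y:
        return CorrelationResult(0.0, n, (0.0, 0.0), 1.0, adjusted=True)
    r, _ = stats.pearsonr(rx, ry)
    df = n - 3  # intercept + covariate + usual Pearson loss
    t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(float(r), n, _fisher_ci(r, n, df_loss=1), float(p),
                             adjusted=True)


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-Z comparison of two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the sign
    follows the first-minus-second convention.  Returns (Z, two-sided p).
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def steiger_z(r_1o: float, r_2o: float, r_12: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing an outcome.

    Tests r(x1, o) against r(x2, o) on the same sample of size ``n``, given
    the correlation r_12 between the two predictors (pooled-estimate variant
    of Steiger 1980).  Returns (Z, two-sided p).
    """
    if n <= 4:
        raise ValueError("n must exceed 4")
    R = np.array([[1.0, r_12, r_1o], [r_12, 1.0, r_2o], [r_1o, r_2o, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")
    z1, z2 = np.arctanh(r_1o), np.arctanh(r_2o)
    rbar = (r_1o + r_2o) / 2.0
    psi = (r_12 * (1.0 - 2.0 * rbar ** 2)
           - 0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r_12 ** 2))
    sbar = psi / (1.0 - rbar ** 2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * sbar))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def group_compare(a, b) -> tuple[float, float, float]:
    """Pooled-variance two-sample t test plus pooled-SD Cohen's d.

    Returns (t, two-sided p, d).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 members")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return float(t), float(p), float(d)
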