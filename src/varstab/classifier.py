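"""Two-feature logistic pathogenicity classifier and ROC machinery.

The classifier combines a truncated stability change (ddG, kcal/mol) and a
rank-normalized evolutionary sequence energy in a plain (unregularized)
logistic regression,

    p(pathogenic) = sigmoid(w_ddg * ddg + w_evo * evo + b),

fit by iteratively reweighted least squares from a zero start, so fits are
deterministic. Evaluation follows the study design: a leave-one-out
jackknife at probability threshold 0.5, and ROC/AUC where the AUC is the
tie-corrected rank statistic and its spread is estimated over repeated
class-balanced subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .variants import VariantTable, clinvar_binary_label

__all__ = [
    "ClassifierModel",
    "JackknifeResult",
    "RocResult",
    "fit_logistic",
    "jackknife",
    "auc",
    "balanced_auc",
    "roc_points",
    "compare_predictors",
]


@dataclass
class ClassifierModel:
    """Fitted logistic model: weights, intercept, and fit diagnostics."""

    weights: np.ndarray  # per-feature weights
    intercept: float
    converged: bool
    separation: bool = False
    std_errors: np.ndarray | None = None  # (k + 1,): weights then intercept
    n_iter: int = 0

    @property
    def w_ddg(self) -> float:
        return float(self.weights[0])

    @property
    def w_evo(self) -> float:
        return float(self.weights[1])

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = np.asarray(features, dtype=float) @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, features: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(features) > threshold).astype(int)


_BETA_CAP = 1e3


def fit_logistic(
    features: np.ndarray,
    labels: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ClassifierModel:
    """Unregularized maximum-likelihood logistic fit by IRLS (zero init).

    Requires n >= 3, both classes present, and no NA features. Perfect
    separation is not an error: the model is returned with the separation
    flag set and coefficients capped at the last stable iterate.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, k) matching labels")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NA values in features or labels")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    n, k = X.shape
    Xd = np.hstack([X, np.ones((n, 1))])
    beta = np.zeros(k + 1)
    converged = False
    separation = False
    n_iter = 0
    cov = None
    for n_iter in range(1, max_iter + 1):
        z = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-z))
        grad = Xd.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        W = p * (1.0 - p)
        H = Xd.T @ (Xd * W[:, None])
        # lstsq handles degenerate feature columns (e.g. all-zero features)
        step, *_ = np.linalg.lstsq(H, grad, rcond=None)
        candidate = beta + step
        if np.max(np.abs(candidate)) > _BETA_CAP or not np.all(np.isfinite(candidate)):
            separation = True
            break
        beta = candidate
    z = Xd @ beta
    p = 1.0 / (1.0 + np.exp(-z))
    if np.all(np.abs(p - y) < 1e-6):
        # perfect prediction: the MLE diverges, flag instead of iterating on
        separation = True
    W = p * (1.0 - p)
    H = Xd.T @ (Xd * W[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = None
    return ClassifierModel(
        weights=beta[:k],
        intercept=float(beta[k]),
        converged=converged,
        separation=separation,
        std_errors=se,
        n_iter=n_iter,
    )


@dataclass
class JackknifeResult:
    """Leave-one-out evaluation: per-point category and overall accuracy."""

    categories: list[str | None]  # TP/FN/FP/TN, None = unclassifiable
    accuracy: float

    def counts(self) -> dict[str, int]:
        out = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
        for c in self.categories:
            if c is not None:
                out[c] += 1
        return out


def jackknife(
    features: np.ndarray, labels: Sequence[int], threshold: float = 0.5
) -> JackknifeResult:
    """Classify each point with a model trained on all other points.

    A left-out point whose training set collapses to a single class is
    marked unclassifiable and dropped from the accuracy denominator.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    categories: list[str | None] = []
    correct = 0
    usable = 0
    for i in range(n):
        mask = np.arange(n) != i
        if len(np.unique(y[mask])) < 2:
            warnings.warn(
                f"jackknife point {i}: single-class training set, unclassifiable"
            )
            categories.append(None)
            continue
        model = fit_logistic(X[mask], y[mask])
        pred = int(model.predict_proba(X[i : i + 1])[0] > threshold)
        if y[i] == 1:
            categories.append("TP" if pred == 1 else "FN")
        else:
            categories.append("FP" if pred == 1 else "TN")
        usable += 1
        correct += int(pred == y[i])
    if usable == 0:
        raise ValueError("no classifiable points")
    return JackknifeResult(categories=categories, accuracy=correct / usable)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-corrected rank-statistic AUC: P(s+ > s-) + 0.5 * P(s+ = s-)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class RocResult:
    """ROC curve with AUC and its balanced-resampling spread."""

    points: list[tuple[float, float]]  # (FPR, TPR) from (0,0) to (1,1)
    auc: float
    auc_std: float | None = None
    n_resamples: int = 0
    seed: int | None = None


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve swept over unique score values, tied scores grouped.

    The trapezoidal area under the returned curve equals :func:`auc`
    exactly (ties produce diagonal segments).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    value = auc(s, y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return RocResult(points=points, auc=value)


def balanced_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_resamples: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and std of AUC over class-balanced subsamples.

    Each resample keeps the minority class whole and draws an equal-size
    majority subset without replacement; fully determined by ``seed``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_resamples):
        chosen = rng.choice(majority, size=len(minority), replace=False)
        idx = np.concatenate([minority, chosen])
        aucs.append(auc(s[idx], y[idx]))
    arr = np.asarray(aucs)
    std = 0.0 if np.ptp(arr) == 0 else float(np.std(arr))
    return float(np.mean(arr)), std


def compare_predictors(
    table: VariantTable,
    methods: Sequence[str],
    n_resamples: int = 100,
    seed: int = 0,
) -> dict[str, RocResult]:
    """Balanced-resampling ROC per score column, identical seeds per method.

    Labels come from the ClinVar binary grouping; VUS/unlabeled records are
    excluded, and per-method NA rows are dropped for that method only.
    Methods name either the core feature fields (``ddg_kcal_mol``,
    ``evo_energy``, ``evo_raw``) or any pass-through annotation column.
    """
    results: dict[str, RocResult] = {}
    for method in methods:
        scores, labels = [], []
        for r in table:
            lab = clinvar_binary_label(r.clinvar_class)
            if lab == "excluded":
                continue
            if method == "ddg_kcal_mol":
                v = r.ddg
            elif method == "evo_energy":
                v = r.evo_energy
            elif method == "evo_raw":
                v = r.evo_raw
            elif method in r.extras:
                raw = str(r.extras[method]).strip()
                v = None if raw in ("", ".", "NA") else float(raw)
            else:
                available = sorted(
                    {"ddg_kcal_mol", "evo_energy", "evo_raw"}
                    | {c for rec in table for c in rec.extras}
                )
                raise KeyError(
                    f"unknown method column {method!r}; available: {available}"
                )
            if v is None:
                continue
            scores.append(v)
            labels.append(1 if lab == "positive" else 0)
        roc = roc_points(scores, labels)
        mean_auc, std_auc = balanced_auc(scores, labels, n_resamples, seed)
        results[method] = RocResult(
            points=roc.points,
            auc=roc.auc,
            auc_std=std_auc,
            n_resamples=n_resamples,
            seed=seed,
        )
    return results
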