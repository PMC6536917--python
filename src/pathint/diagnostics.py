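"""Cross-validated diagnostic classification and ROC machinery.

Participants are scored by a linear classifier (logistic by default, linear
discriminant analysis as an option) on a per-participant feature vector —
typically the mean absolute distance error plus age, sex and education —
under stratified k-fold cross-validation (k = 10), so every participant is
scored exactly once by a model never trained on them.  The cross-validated
posterior probabilities feed an empirical ROC; the area under it equals the
normalized Mann-Whitney U statistic with ties counted one half.  Confidence
intervals come from a stratified participant-level bootstrap that re-runs
the full cross-validation inside every replicate.  The optimal operating
point maximizes Youden's J (sensitivity + specificity - 1), ties broken
toward higher specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ClassifierSpec",
    "ROCResult",
    "crossval_posteriors",
    "roc_from_scores",
    "bootstrap_roc",
    "threshold_report",
    "plot_roc",
]

DEFAULT_FEATURES = ("mean_abs_error", "age", "sex01", "education")


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear classification setup for one diagnostic contrast."""

    features: tuple = DEFAULT_FEATURES
    model: str = "logistic"  # or "lda"
    k_folds: int = 10
    stratified: bool = True
    bootstrap_reps: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.model not in ("logistic", "lda"):
            raise ValueError("model must be 'logistic' or 'lda'")

    def validate_for(self, labels: np.ndarray) -> None:
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {len(classes)}")
        if self.stratified and self.k_folds > counts.min():
            raise ValueError(
                f"k_folds={self.k_folds} exceeds the smaller class size "
                f"({counts.min()}); folds would lose a class"
            )


@dataclass
class ROCResult:
    """Empirical ROC with optional bootstrap confidence bounds."""

    auc: float
    fpr: np.ndarray  # monotone non-decreasing, from 0 to 1
    tpr: np.ndarray
    thresholds: np.ndarray  # score >= threshold predicts positive
    optimal_threshold: float
    sensitivity_at_opt: float
    specificity_at_opt: float
    ci_low: float | None = None
    ci_high: float | None = None
    tpr_grid_fpr: np.ndarray | None = None  # FPR grid of the pointwise band
    tpr_ci_low: np.ndarray | None = None
    tpr_ci_high: np.ndarray | None = None
    fold_assignments: np.ndarray | None = None


def _classifier(spec: ClassifierSpec):
    if spec.model == "lda":
        clf = LinearDiscriminantAnalysis()
    else:
        clf = LogisticRegression(C=100.0, max_iter=5000)
    return make_pipeline(StandardScaler(), clf)


def crossval_posteriors(
    features: pd.DataFrame, labels: np.ndarray, spec: ClassifierSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold posterior probability of the positive class per participant.

    Returns ``(posteriors, fold_assignments)``; deterministic for a fixed
    ``spec.rng_seed``.
    """
    y = np.asarray(labels).astype(int)
    spec.validate_for(y)
    X = features.loc[:, list(spec.features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    splitter = StratifiedKFold(
        n_splits=spec.k_folds, shuffle=True, random_state=spec.rng_seed % (2**31)
    )
    post = np.full(len(y), np.nan)
    folds = np.full(len(y), -1)
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {k} training set lost a class")
        clf = _classifier(spec)
        clf.fit(X[tr], y[tr])
        post[te] = clf.predict_proba(X[te])[:, 1]
        folds[te] = k
    return post, folds


def roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Empirical ROC over all score thresholds; AUC by the trapezoid rule.

    Tied scores produce diagonal segments, so the AUC equals the normalized
    Mann-Whitney U statistic with ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # indices of the last occurrence of each distinct score
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))  # first max = smallest FPR = highest specificity
    return ROCResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        optimal_threshold=float(thresholds[best]),
        sensitivity_at_opt=float(tpr[best]),
        specificity_at_opt=float(1.0 - fpr[best]),
    )


def bootstrap_roc(
    features: pd.DataFrame, labels: np.ndarray, spec: ClassifierSpec
) -> ROCResult:
    """Full CV-scored ROC with percentile bootstrap confidence intervals.

    Participants are resampled with replacement within each class (so no
    replicate loses a class), and the entire cross-validation scoring is
    re-run per replicate.  95% percentile bounds are reported for the AUC and
    for the TPR on a fixed FPR grid.
    """
    y = np.asarray(labels).astype(int)
    spec.validate_for(y)
    post, folds = crossval_posteriors(features, y, spec)
    result = roc_from_scores(post, y)
    result.fold_assignments = folds

    rng = np.random.default_rng(spec.rng_seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    grid = np.linspace(0.0, 1.0, 101)
    aucs = np.empty(spec.bootstrap_reps)
    tpr_grid = np.empty((spec.bootstrap_reps, grid.size))
    feats = features.reset_index(drop=True)
    for b in range(spec.bootstrap_reps):
        take = np.r_[
            rng.choice(idx_pos, size=idx_pos.size, replace=True),
            rng.choice(idx_neg, size=idx_neg.size, replace=True),
        ]
        fb = feats.iloc[take].reset_index(drop=True)
        yb = y[take]
        sub = ClassifierSpec(
            features=spec.features,
            model=spec.model,
            k_folds=spec.k_folds,
            stratified=spec.stratified,
            bootstrap_reps=1,
            rng_seed=int(rng.integers(2**31)),
        )
        pb, _ = crossval_posteriors(fb, yb, sub)
        rb = roc_from_scores(pb, yb)
        aucs[b] = rb.auc
        tpr_grid[b] = np.interp(grid, rb.fpr, rb.tpr)
    result.ci_low, result.ci_high = (
        float(np.percentile(aucs, 2.5)),
        float(np.percentile(aucs, 97.5)),
    )
    result.tpr_grid_fpr = grid
    result.tpr_ci_low = np.percentile(tpr_grid, 2.5, axis=0)
    result.tpr_ci_high = np.percentile(tpr_grid, 97.5, axis=0)
    return result


def plot_roc(result: ROCResult, path, title: str = "ROC") -> None:
    """Write a simple ROC curve (with the pointwise band when present)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if result.tpr_grid_fpr is not None:
        ax.fill_between(result.tpr_grid_fpr, result.tpr_ci_low, result.tpr_ci_high,
                        alpha=0.2, color="tab:red", label="95% bootstrap band")
    ax.plot(result.fpr, result.tpr, color="tab:red",
            label=f"AUC = {result.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    best = int(np.argmax(result.tpr - result.fpr))
    ax.plot(result.fpr[best], result.tpr[best], "k*", ms=10)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def threshold_report(
    errors: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """Sensitivity and specificity of the rule ``error >= threshold -> positive``.

    ``threshold`` is in metres (the scale of the mean absolute distance
    error).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    e = np.asarray(errors, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = e[y == 1]
    neg = e[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    sensitivity = float(np.mean(pos >= threshold))
    specificity = float(np.mean(neg < threshold))
    return sensitivity, specificity
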