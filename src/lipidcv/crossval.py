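"""Repeated stratified cross-validated risk prediction.

The prediction harness mirrors a widely used omics biomarker-discovery
design: class-stratified k-fold cross-validation (default 3-fold)
repeated many times (default 400 repeats, so 1200 trials), with
univariate ROC-AUC feature selection and per-feature standardization
performed inside each training fold only, feeding a soft-margin linear
support vector machine. Per-trial performance (accuracy, AUC,
sensitivity, specificity, PPV, NPV) is aggregated to means with 95%
confidence intervals, and feature stability is summarised as the
percentage of trials in which each feature was selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054

__all__ = [
    "CVConfig",
    "LinearClassifier",
    "TrialMetrics",
    "AggStat",
    "stratified_folds",
    "auc_rank",
    "rank_features",
    "train_linear_svm",
    "confusion_metrics",
    "run_single_trial",
    "run_repeated_cv",
    "aggregate_trials",
    "select_model_size",
    "inclusion_table",
]

METRIC_NAMES = ("accuracy", "auc", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 3
    repeats: int = 400
    max_features: int = 30
    classifier_c: float = 1.0
    decision_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if not (self.classifier_c > 0):
            raise ValueError("classifier_c must be > 0")


@dataclass
class LinearClassifier:
    """A trained linear decision function with its training-fold scaling."""

    weights: np.ndarray
    bias: float
    feature_ids: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[list(self.feature_ids)].to_numpy(dtype=float) - self.center) / self.scale
        return Z @ self.weights + self.bias


@dataclass
class TrialMetrics:
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    selected_feature_ids: tuple[str, ...] = ()
    trial_index: int = -1
    repeat_index: int = -1
    fold_index: int = -1


@dataclass
class AggStat:
    mean: float
    ci95_low: float
    ci95_high: float
    n_used: int


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each sample a fold index 0..k-1, stratified by class.

    Per class, fold sizes differ by at most one; the assignment is a
    deterministic function of the rng state.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_train, test) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test] = fold
    return assignment


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Midrank ROC AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _feature_aucs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # vectorised midrank AUC per column
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(X, axis=0)
    u = ranks[pos].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def rank_features(train_matrix: pd.DataFrame, train_labels: np.ndarray) -> list[str]:
    """Order features by decreasing two-sided discrimination |AUC - 0.5|.

    Anti-discriminating features (AUC below 0.5) rank as highly as their
    mirror images above 0.5, since a margin classifier can use either
    sign. Ties (including constant features at AUC exactly 0.5) break by
    feature id, lexicographically, so the order is deterministic. Uses
    training data only; callers must not pass held-out rows.
    """
    y = np.asarray(train_labels)
    X = train_matrix.to_numpy(dtype=float)
    aucs = _feature_aucs(X, y)
    const = (X.max(axis=0) - X.min(axis=0)) == 0
    if const.any():
        logger.debug(
            "constant features ranked last (AUC 0.5): %s",
            [train_matrix.columns[i] for i in np.flatnonzero(const)],
        )
    dev = np.abs(aucs - 0.5)
    order = sorted(range(len(dev)), key=lambda i: (-dev[i], train_matrix.columns[i]))
    return [train_matrix.columns[i] for i in order]


def train_linear_svm(X: np.ndarray, y: np.ndarray, c: float = 1.0) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM: minimize 0.5 ||w||^2 + c * sum hinge.

    ``y`` in {-1, +1}; ``X`` should already be centered/scaled with
    training-fold statistics. Returns (weights, bias).
    """
    y = np.asarray(y)
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be in {-1, +1}")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    clf = SVC(kernel="linear", C=c, tol=1e-6)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def svm_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, c: float) -> float:
    """Primal soft-margin objective 0.5||w||^2 + c * sum hinge(y f(x))."""
    margins = y * (X @ w + b)
    return 0.5 * float(w @ w) + c * float(np.maximum(0.0, 1.0 - margins).sum())


def confusion_metrics(
    decision_values: Sequence[float], labels: Sequence[int], threshold: float = 0.0
) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/PPV/NPV (percent) at a threshold.

    Predictions are positive when the decision value exceeds the
    threshold. Ratios with a zero denominator are reported as NaN
    (missing), never as zero.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    pred = d > threshold
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def run_single_trial(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    feature_count: int,
    c: float = 1.0,
    threshold: float = 0.0,
) -> tuple[TrialMetrics, LinearClassifier]:
    """One train/test trial: in-fold selection, scaling, SVM, metrics.

    Feature ranking and standardization parameters are computed from the
    training rows only; the held-out rows are touched only to be scored.
    """
    if feature_count < 1:
        raise ValueError("feature_count must be >= 1")
    y = np.asarray(labels)
    X_train = matrix.iloc[train_idx]
    y_train = y[train_idx]
    selected = tuple(rank_features(X_train, y_train)[:feature_count])

    A = X_train[list(selected)].to_numpy(dtype=float)
    center = A.mean(axis=0)
    scale = A.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (A - center) / scale
    y_pm = np.where(y_train == 1, 1, -1)
    w, b = train_linear_svm(Z, y_pm, c=c)
    clf = LinearClassifier(w, b, selected, center, scale)

    d_test = clf.decision_values(matrix.iloc[test_idx])
    y_test = y[test_idx]
    cm = confusion_metrics(d_test, y_test, threshold)
    metrics = TrialMetrics(
        accuracy=cm["accuracy"],
        auc=auc_rank(d_test, y_test),
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        ppv=cm["ppv"],
        npv=cm["npv"],
        selected_feature_ids=selected,
    )
    return metrics, clf


def run_repeated_cv(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    feature_count: int,
    config: CVConfig,
) -> tuple[list[TrialMetrics], dict[str, int]]:
    """Repeated stratified k-fold cross-validation.

    Each repeat draws a fresh stratified partition; each fold serves as
    the test set exactly once per repeat, so the total number of trials
    is ``k_folds * repeats``. Returns the per-trial metrics stream and
    the per-feature selection counts. Fully reproducible from the seed.
    """
    if feature_count < 1:
        raise ValueError("feature_count must be >= 1")
    if feature_count > matrix.shape[1]:
        raise ValueError(
            f"feature_count {feature_count} exceeds available features {matrix.shape[1]}"
        )
    y = np.asarray(labels)
    trials: list[TrialMetrics] = []
    counts: dict[str, int] = {}
    children = np.random.SeedSequence(config.seed).spawn(config.repeats)
    t = 0
    for r in range(config.repeats):
        rng = np.random.default_rng(children[r])
        assignment = stratified_folds(y, config.k_folds, rng)
        for fold in range(config.k_folds):
            test_idx = np.flatnonzero(assignment == fold)
            train_idx = np.flatnonzero(assignment != fold)
            metrics, _clf = run_single_trial(
                matrix,
                y,
                train_idx,
                test_idx,
                feature_count,
                c=config.classifier_c,
                threshold=config.decision_threshold,
            )
            metrics.trial_index, metrics.repeat_index, metrics.fold_index = t, r, fold
            trials.append(metrics)
            for f in metrics.selected_feature_ids:
                counts[f] = counts.get(f, 0) + 1
            t += 1
    return trials, counts


def aggregate_trials(trials: Sequence[TrialMetrics]) -> dict[str, AggStat]:
    """Per-metric mean and normal-approximation 95% CI over trials.

    Missing (NaN) values — e.g. PPV in trials with no positive
    prediction — are excluded metric-wise, with the used count reported.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to aggregate")
    out: dict[str, AggStat] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(tr, name) for tr in trials], dtype=float)
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        if n == 0:
            out[name] = AggStat(float("nan"), float("nan"), float("nan"), 0)
            continue
        mean = float(vals.mean())
        half = float(Z_95 * vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out[name] = AggStat(mean, mean - half, mean + half, n)
    return out


def _smallest_argmax(curve: Sequence[float]) -> int:
    """Index (1-based size) of the smallest count attaining the max mean AUC."""
    arr = np.asarray(curve, dtype=float)
    return int(np.flatnonzero(arr == np.nanmax(arr))[0]) + 1


def select_model_size(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config: CVConfig,
    repeats: int | None = None,
) -> tuple[int, np.ndarray]:
    """Scan candidate feature counts 1..max_features for the best mean AUC.

    Runs the repeated-CV harness once per candidate count (optionally
    with a reduced number of repeats) using the same seed, so all sizes
    see the same sequence of partitions. Returns the smallest count
    attaining the maximal mean AUC (parsimony tie-break) and the full
    AUC-versus-size curve.
    """
    max_f = min(config.max_features, matrix.shape[1])
    cfg = CVConfig(
        k_folds=config.k_folds,
        repeats=repeats or config.repeats,
        max_features=config.max_features,
        classifier_c=config.classifier_c,
        decision_threshold=config.decision_threshold,
        seed=config.seed,
    )
    curve = np.empty(max_f)
    for m in range(1, max_f + 1):
        trials, _ = run_repeated_cv(matrix, labels, m, cfg)
        curve[m - 1] = np.nanmean([tr.auc for tr in trials])
    return _smallest_argmax(curve), curve


def inclusion_table(selection_counts: Mapping[str, int], n_trials: int) -> pd.DataFrame:
    """Feature inclusion frequencies (% of trials), ranked descending.

    Ties in frequency are broken by feature id so the ranking is
    deterministic.
    """
    for f, cnt in selection_counts.items():
        if cnt > n_trials:
            raise ValueError(f"selection count for {f!r} exceeds n_trials")
        if cnt < 0:
            raise ValueError("selection counts must be >= 0")
    rows = sorted(
        ((100.0 * cnt / n_trials, f) for f, cnt in selection_counts.items()),
        key=lambda t: (-t[0], t[1]),
    )
    return pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "feature_id": [f for _freq, f in rows],
            "inclusion_frequency_pct": [freq for freq, _f in rows],
        }
    )
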