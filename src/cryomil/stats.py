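"""Evaluation statistics: ROC/AUC, dual threshold selection, DeLong CIs,
permutation significance, fold comparisons, cross-validation planning, and
probability-level ensemble voting.

Conventions: the score is the probability of the positive (mutant) class and
a prediction is positive iff score >= threshold. AUC is the Mann-Whitney
probability that a random positive outscores a random negative, ties counted
one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import ConfigurationError, DegenerateInputError, DimensionMismatchError
from .synthetic import SlideRecord


@dataclass
class EvalReport:
    task: str
    auc: float
    ci: tuple[float, float]
    ci_method: str  # "DeLong" | "fold-spread"
    permutation_p: float | None
    balanced_threshold: float
    acc: float
    sen: float
    spe: float
    f1_threshold: float
    f1: float
    n_pos: int
    n_neg: int
    fold: str = "pooled"


@dataclass
class FoldPlan:
    folds: list[set[str]]  # patient-id sets, one per fold
    ratio: str
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise DegenerateInputError("both classes must be present")


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC, equal to the tie-corrected Mann-Whitney probability."""
    ranks = sps.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the ROC curve points (fpr, tpr)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return _auc_mann_whitney(scores, labels), fpr, tpr


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.unique(np.concatenate([u, mids, [u[-1] + 1.0]]))


def _confusion(scores, labels, thr):
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def balanced_threshold(
    scores, labels, criterion: str = "youden"
) -> tuple[float, float, float, float]:
    """Threshold balancing sensitivity and specificity.

    ``criterion="youden"`` maximises J = SEN + SPE - 1 (default);
    ``criterion="min_diff"`` minimises |SEN - SPE|. Ties take the lower
    threshold. Returns (threshold, ACC, SEN, SPE).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    if criterion not in ("youden", "min_diff"):
        raise ConfigurationError("criterion must be 'youden' or 'min_diff'")
    best = None
    for thr in _threshold_candidates(scores):
        tp, fp, fn, tn = _confusion(scores, labels, thr)
        sen = tp / (tp + fn)
        spe = tn / (tn + fp)
        key = (sen + spe - 1.0) if criterion == "youden" else -abs(sen - spe)
        if best is None or key > best[0] + 1e-12:
            acc = (tp + tn) / labels.size
            best = (key, thr, acc, sen, spe)
    return best[1], best[2], best[3], best[4]


def f1_threshold(scores, labels) -> tuple[float, float]:
    """Threshold maximising F1; ties take the lower threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    best = None
    for thr in _threshold_candidates(scores):
        tp, fp, fn, _ = _confusion(scores, labels, thr)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if best is None or f1 > best[0] + 1e-12:
            best = (f1, thr)
    return best[1], best[0]


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong structural-components CI for the AUC, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise DegenerateInputError("DeLong CI needs >= 2 samples per class")
    # structural components: V10 over positives, V01 over negatives
    v10 = np.empty(m)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n
    v01 = np.empty(n)
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / m
    auc = v10.mean()
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def permutation_pvalue(
    scores, labels, n_perm: int = 1000, seed: int = 0
) -> float:
    """One-sided permutation p for AUC > chance.

    p = (1 + #{AUC_perm >= AUC_obs}) / (n_perm + 1). For cross-validation
    results, pass the predictions and labels pooled over all folds.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    obs = _auc_mann_whitney(scores, labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _auc_mann_whitney(scores, perm) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def compare_models_ttest(fold_aucs_a, fold_aucs_b) -> float:
    """One-sided Welch two-sample t-test of mean(a) > mean(b) over fold AUCs."""
    a = np.asarray(fold_aucs_a, dtype=np.float64)
    b = np.asarray(fold_aucs_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("need >= 2 folds per model")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.5
        return 0.0 if a.mean() > b.mean() else 1.0
    res = sps.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)


def ensemble_vote(probability_matrix) -> np.ndarray:
    """Probability-level majority voting: column means over models."""
    rows = [np.asarray(r, dtype=np.float64) for r in probability_matrix]
    if len({r.shape for r in rows}) > 1:
        raise DimensionMismatchError("all model rows must have the same length")
    return np.mean(rows, axis=0)


def make_folds(
    records: list[SlideRecord],
    k: int,
    task: str,
    seed: int = 0,
    ratio: str | None = None,
) -> FoldPlan:
    """Patient-level stratified k-fold plan.

    All slides of a patient share a fold; stratification is on the
    patient-level task label (a gene name, or ``"PA"``).
    """
    patients: dict[str, int] = {}
    for r in records:
        if task == "PA":
            y = int(r.pa_label)
        else:
            if task not in r.gene_labels:
                raise ConfigurationError(f"task '{task}' not in gene labels")
            y = int(r.gene_labels[task] == "mutant")
        prev = patients.setdefault(r.patient_id, y)
        if prev != y:
            raise ConfigurationError(
                f"patient {r.patient_id} has inconsistent labels for {task}"
            )
    ids = sorted(patients)
    if k > len(ids):
        raise ConfigurationError(f"k={k} exceeds number of patients ({len(ids)})")
    rng = np.random.default_rng(seed)
    # Deal patients round-robin, class by class with a continuous fold cursor:
    # fold sizes and per-fold class counts both end up within 1 of proportional.
    folds: list[set[str]] = [set() for _ in range(k)]
    cursor = 0
    for cls in (0, 1):
        members = [p for p in ids if patients[p] == cls]
        rng.shuffle(members)
        for p in members:
            folds[cursor % k].add(p)
            cursor += 1
    return FoldPlan(folds=folds, ratio=ratio or f"{k - 1}:1", seed=seed)


def evaluate_task(
    scores,
    labels,
    task: str = "task",
    n_perm: int = 1000,
    seed: int = 0,
    ci_method: str = "DeLong",
    fold_aucs=None,
    fold: str = "pooled",
) -> EvalReport:
    """Assemble the standard report for one prediction task.

    ``ci_method="fold-spread"`` uses a t-interval over the supplied per-fold
    AUCs instead of the DeLong interval on the pooled scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    auc, _, _ = roc_auc(scores, labels)
    if ci_method == "fold-spread":
        if fold_aucs is None or len(fold_aucs) < 2:
            raise ConfigurationError("fold-spread CI needs per-fold AUCs")
        fa = np.asarray(fold_aucs, dtype=np.float64)
        se = fa.std(ddof=1) / np.sqrt(fa.size)
        t = sps.t.ppf(0.975, fa.size - 1)
        ci = (max(0.0, fa.mean() - t * se), min(1.0, fa.mean() + t * se))
    else:
        ci = delong_ci(scores, labels)
    p = permutation_pvalue(scores, labels, n_perm=n_perm, seed=seed) if n_perm else None
    thr, acc, sen, spe = balanced_threshold(scores, labels)
    fthr, f1 = f1_threshold(scores, labels)
    return EvalReport(
        task=task,
        auc=auc,
        ci=ci,
        ci_method=ci_method,
        permutation_p=p,
        balanced_threshold=thr,
        acc=acc,
        sen=sen,
        spe=spe,
        f1_threshold=fthr,
        f1=f1,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
        fold=fold,
    )
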