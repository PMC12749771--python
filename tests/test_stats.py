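import numpy as np
import pytest
from scipy import stats as sps

import cryomil as cm
from cryomil.errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionMismatchError,
)


def _pair_auc(scores, labels):
    """O(n^2) pairwise Mann-Whitney oracle, ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def test_auc_trivial_cases():
    auc, _, _ = cm.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    auc, _, _ = cm.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert auc == 0.5
    with pytest.raises(DegenerateInputError):
        cm.roc_auc([0.1, 0.2], [1, 1])


def test_auc_matches_pair_oracle_property(rng):
    for _ in range(200):
        n = int(rng.integers(4, 31))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # coarse grid to force ties
        auc, _, _ = cm.roc_auc(scores, labels)
        assert auc == pytest.approx(_pair_auc(scores, labels), abs=1e-12)


def _exhaustive_balanced(scores, labels):
    best = None
    cands = sorted(set(scores))
    mids = [(a + b) / 2 for a, b in zip(cands, cands[1:])]
    for thr in sorted(set(cands + mids + [max(cands) + 1.0])):
        pred = [s >= thr for s in scores]
        tp = sum(p and y for p, y in zip(pred, labels))
        tn = sum((not p) and (not y) for p, y in zip(pred, labels))
        sen = tp / sum(labels)
        spe = tn / (len(labels) - sum(labels))
        j = sen + spe - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, thr)
    return best[1]


def test_balanced_threshold_matches_exhaustive_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(6, 20))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)
        thr, _, _, _ = cm.balanced_threshold(scores, labels)
        assert thr == pytest.approx(_exhaustive_balanced(list(scores), list(labels)))


def test_balanced_threshold_perfect_separation_and_orientation():
    thr, acc, sen, spe = cm.balanced_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert sen == 1.0 and spe == 1.0 and acc == 1.0
    # reversed scores: orientation stays "positive iff score >= threshold",
    # so the best achievable J on anti-separated data is 0
    thr, _, sen, spe = cm.balanced_threshold([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
    assert sen + spe - 1 == pytest.approx(0.0)


def test_f1_threshold_oracle_and_divergence_from_youden(rng):
    for _ in range(50):
        n = int(rng.integers(6, 20))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)
        thr, f1 = cm.f1_threshold(scores, labels)
        # exhaustive F1 scan
        best = 0.0
        u = sorted(set(scores))
        cands = u + [(a + b) / 2 for a, b in zip(u, u[1:])] + [u[-1] + 1]
        for t in cands:
            pred = scores >= t
            tp = int(np.sum(pred & (labels == 1)))
            fp = int(np.sum(pred & (labels == 0)))
            fn = int(np.sum(~pred & (labels == 1)))
            denom = 2 * tp + fp + fn
            best = max(best, 2 * tp / denom if denom else 0.0)
        assert f1 == pytest.approx(best, abs=1e-12)
    _, f1 = cm.f1_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert f1 == 1.0
    # constructed asymmetric set where the two criteria pick different thresholds
    scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    labels = [0, 1, 0, 1, 1, 1]
    thr_j, _, _, _ = cm.balanced_threshold(scores, labels)
    thr_f, _ = cm.f1_threshold(scores, labels)
    assert thr_j != thr_f


def test_delong_ci_contains_auc_and_clips(rng):
    scores = rng.normal(size=60) + np.repeat([0, 1], 30)
    labels = np.repeat([0, 1], 30)
    auc, _, _ = cm.roc_auc(scores, labels)
    lo, hi = cm.delong_ci(scores, labels)
    assert lo <= auc <= hi
    lo, hi = cm.delong_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert hi == 1.0
    with pytest.raises(DegenerateInputError):
        cm.delong_ci([0.9, 0.2, 0.1], [1, 0, 0])


def test_permutation_p_floor_and_determinism():
    scores = np.concatenate([np.zeros(15), np.ones(15)])
    labels = np.concatenate([np.zeros(15, int), np.ones(15, int)])
    p = cm.permutation_pvalue(scores, labels, n_perm=1000, seed=5)
    assert p == pytest.approx(1 / 1001)
    assert p == cm.permutation_pvalue(scores, labels, n_perm=1000, seed=5)


def test_permutation_p_monotone_in_signal(rng):
    medians = []
    for shift in (0.0, 0.8, 2.0):
        ps = []
        for rep in range(20):
            r = np.random.default_rng(100 * rep + int(shift * 10))
            labels = np.repeat([0, 1], 20)
            scores = r.normal(size=40) + shift * labels
            ps.append(cm.permutation_pvalue(scores, labels, n_perm=200, seed=rep))
        medians.append(np.median(ps))
    assert medians[0] > medians[1] >= medians[2]


def test_fold_ttest_cases():
    a = np.array([0.7, 0.75, 0.8, 0.72, 0.77])
    assert cm.compare_models_ttest(a, a) == pytest.approx(0.5)
    b = a - 0.2
    p = cm.compare_models_ttest(np.tile(a, 2), np.tile(b, 2))
    assert p < 0.01
    # closed-form Welch oracle
    t = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
    df = (a.var(ddof=1) / 5 + b.var(ddof=1) / 5) ** 2 / (
        (a.var(ddof=1) / 5) ** 2 / 4 + (b.var(ddof=1) / 5) ** 2 / 4
    )
    assert cm.compare_models_ttest(a, b) == pytest.approx(sps.t.sf(t, df))
    assert cm.compare_models_ttest(b, a) == pytest.approx(
        1 - cm.compare_models_ttest(a, b)
    )
    with pytest.raises(DegenerateInputError):
        cm.compare_models_ttest([0.5], [0.4, 0.5])


def test_ensemble_vote():
    m = [[0.1, 0.2, 0.3, 0.4]] * 10
    np.testing.assert_allclose(cm.ensemble_vote(m), [0.1, 0.2, 0.3, 0.4])
    hand = [[0.0, 0.3, 0.6, 1.0], [0.2, 0.1, 0.9, 0.8], [0.4, 0.2, 0.0, 0.6]]
    np.testing.assert_allclose(
        cm.ensemble_vote(hand), [0.2, 0.2, 0.5, 0.8]
    )
    out = cm.ensemble_vote(hand)
    assert (out >= 0).all() and (out <= 1).all()
    with pytest.raises(DimensionMismatchError):
        cm.ensemble_vote([[0.1, 0.2], [0.3]])


def _fake_records(n, prevalence=0.4, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        y = "mutant" if rng.random() < prevalence else "wild-type"
        for s in range(1, int(rng.integers(1, 4)) + 1):
            recs.append(
                cm.SlideRecord(
                    slide_id=f"P{i}_S{s}", patient_id=f"P{i}", biopsy_order=s,
                    pass_status="Pass", gene_labels={"G": y}, pa_label=False,
                    centre_id="C0",
                )
            )
    return recs


def test_make_folds_partition_and_balance():
    recs = _fake_records(30)
    plan = cm.make_folds(recs, 10, "G", seed=1)
    sizes = [len(f) for f in plan.folds]
    assert sizes == [3] * 10
    all_patients = set().union(*plan.folds)
    assert len(all_patients) == 30
    assert sum(sizes) == 30  # disjoint partition
    # stratification: per-fold positive counts within 1 of proportional
    pos = {r.patient_id for r in recs if r.gene_labels["G"] == "mutant"}
    target = len(pos) / 10
    for f in plan.folds:
        assert abs(len(f & pos) - target) <= 1
    # determinism and error case
    plan2 = cm.make_folds(recs, 10, "G", seed=1)
    assert plan.folds == plan2.folds
    with pytest.raises(ConfigurationError):
        cm.make_folds(recs, 31, "G")


def test_pooled_metrics_equal_concatenated_fold_metrics(rng):
    # definition check: pooling scores over folds = metrics on the concatenation
    scores = rng.random(40)
    labels = rng.integers(0, 2, size=40)
    labels[:2] = [0, 1]
    parts = [(scores[:20], labels[:20]), (scores[20:], labels[20:])]
    concat_s = np.concatenate([p[0] for p in parts])
    concat_l = np.concatenate([p[1] for p in parts])
    auc_a, _, _ = cm.roc_auc(concat_s, concat_l)
    auc_b, _, _ = cm.roc_auc(scores, labels)
    assert auc_a == auc_b


def test_evaluate_task_report_invariants(rng):
    scores = np.clip(rng.normal(0.5, 0.2, size=40) + 0.2 * np.repeat([0, 1], 20), 0, 1)
    labels = np.repeat([0, 1], 20)
    rep = cm.evaluate_task(scores, labels, task="G", n_perm=200, seed=0)
    assert 0 <= rep.auc <= 1
    assert rep.ci[0] <= rep.auc <= rep.ci[1]
    for v in (rep.acc, rep.sen, rep.spe, rep.f1):
        assert 0 <= v <= 1
    assert rep.n_pos == 20 and rep.n_neg == 20
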