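"""Retrospective biopsy re-checking simulation.

Replays each patient's cryosection slides in their intraoperative arrival
order and compares two stopping rules: the human rule (biopsy until the
first Pass slide) and the AI rule (stop at the first slide on which the
classifier correctly flags a truly mutant gene). Patients with no mutant
gene, and mutant patients the model never flags, fall back to the human
count, so the AI count never exceeds the human count and the reduction
ratio is nonnegative. The analysis is optimistic by construction — during a
real operation ground-truth mutation status is unknown — and results carry
that caveat flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError
from . import stats as ev

OPTIMISTIC_CAVEAT = (
    "retrospective upper bound: assumes ground-truth mutation status is "
    "knowable at re-check time"
)


@dataclass
class StreamSlide:
    biopsy_order: int
    pass_status: str  # "Pass" | "No-Pass"
    probabilities: dict[str, float]  # gene -> P(mutant)


@dataclass
class PatientStream:
    patient_id: str
    gene_truth: dict[str, str]  # gene -> "mutant" | "wild-type"
    slides: list[StreamSlide]

    def __post_init__(self) -> None:
        orders = [s.biopsy_order for s in self.slides]
        if orders != sorted(orders) or len(set(orders)) != len(orders):
            raise ConfigurationError(
                f"slides of {self.patient_id} must be strictly ordered"
            )


@dataclass
class RebiopsyResult:
    human_counts: np.ndarray
    ai_counts: np.ndarray  # capped at the human count
    ai_counts_raw: np.ndarray  # first-detection counts without the cap
    total_human: int
    total_ai: int
    saved: int
    mean_human: float
    mean_ai: float
    reduction_ratio: float  # saved / total_human
    t_statistic: float
    df: int
    p_value: float
    sankey_counts: dict[tuple[int, int], int]
    caveat: str = OPTIMISTIC_CAVEAT
    per_patient: list[str] = field(default_factory=list)


def human_biopsy_count(stream: PatientStream) -> int:
    """1-based index of the first Pass slide; total count if none passes."""
    if not stream.slides:
        raise ConfigurationError(f"patient {stream.patient_id} has no slides")
    for i, s in enumerate(stream.slides, start=1):
        if s.pass_status == "Pass":
            return i
    return len(stream.slides)


def ai_biopsy_count(
    stream: PatientStream,
    thresholds: dict[str, float],
    mode: str = "strict",
    cap: bool = True,
) -> int:
    """1-based order of the first slide on which the model fires.

    ``mode="strict"`` requires gene-matched correctness: some gene that is
    truly mutant for this patient has probability >= its threshold.
    ``mode="lenient"`` accepts any above-threshold gene call. Patients with
    no mutant gene (strict mode), and patients never flagged, fall back to
    the human count; with ``cap=False`` the raw first-detection order is
    returned and never-flagged patients still fall back.
    """
    if mode not in ("strict", "lenient"):
        raise ConfigurationError("mode must be 'strict' or 'lenient'")
    human = human_biopsy_count(stream)
    mutant_genes = [g for g, v in stream.gene_truth.items() if v == "mutant"]
    if mode == "strict" and not mutant_genes:
        return human
    genes = mutant_genes if mode == "strict" else list(stream.gene_truth)
    for i, s in enumerate(stream.slides, start=1):
        for g in genes:
            if g not in s.probabilities:
                raise ConfigurationError(
                    f"missing probability for gene {g} on slide {i} of "
                    f"{stream.patient_id}"
                )
            if g not in thresholds:
                raise ConfigurationError(f"missing threshold for gene {g}")
            if s.probabilities[g] >= thresholds[g]:
                return min(i, human) if cap else i
    return human


def reduction_summary(
    streams: list[PatientStream],
    thresholds: dict[str, float],
    mode: str = "strict",
) -> RebiopsyResult:
    """Human-vs-AI biopsy count comparison over a cohort of patient streams."""
    human = np.array([human_biopsy_count(s) for s in streams], dtype=np.int64)
    ai = np.array(
        [ai_biopsy_count(s, thresholds, mode=mode) for s in streams], dtype=np.int64
    )
    raw = np.array(
        [ai_biopsy_count(s, thresholds, mode=mode, cap=False) for s in streams],
        dtype=np.int64,
    )
    return summarize_counts(
        human, ai, raw_ai=raw, patient_ids=[s.patient_id for s in streams]
    )


def summarize_counts(
    human_counts,
    ai_counts,
    raw_ai=None,
    patient_ids: list[str] | None = None,
) -> RebiopsyResult:
    """Reduction statistics from per-patient (human, AI) biopsy counts."""
    human = np.asarray(human_counts, dtype=np.int64)
    ai = np.asarray(ai_counts, dtype=np.int64)
    if human.shape != ai.shape:
        raise ConfigurationError("human and AI count vectors must align")
    if np.any(ai > human):
        raise ConfigurationError("capped AI counts cannot exceed human counts")
    n = human.size
    if n == 0:
        raise DegenerateInputError("no patients")
    total_h, total_a = int(human.sum()), int(ai.sum())
    saved = total_h - total_a
    if n >= 2 and np.any(human != ai):
        res = sps.ttest_rel(human, ai, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
    else:
        if n < 2:
            warnings.warn("fewer than 2 patients: paired t-test not computed")
        t, p = float("nan"), float("nan")
    sankey: dict[tuple[int, int], int] = {}
    for h, a in zip(human, ai):
        sankey[(int(h), int(a))] = sankey.get((int(h), int(a)), 0) + 1
    return RebiopsyResult(
        human_counts=human,
        ai_counts=ai,
        ai_counts_raw=np.asarray(raw_ai, dtype=np.int64) if raw_ai is not None else ai,
        total_human=total_h,
        total_ai=total_a,
        saved=saved,
        mean_human=total_h / n,
        mean_ai=total_a / n,
        reduction_ratio=saved / total_h if total_h else 0.0,
        t_statistic=t,
        df=n - 1,
        p_value=p,
        sankey_counts=sankey,
        per_patient=patient_ids or [],
    )


def sankey_counts(result: RebiopsyResult) -> dict[tuple[int, int], int]:
    """Transition counts (human_count, ai_count) -> n patients."""
    return dict(result.sankey_counts)


def early_biopsy_metrics(
    streams: list[PatientStream],
    gene: str,
    n_perm: int = 0,
    seed: int = 0,
) -> dict[str, ev.EvalReport]:
    """Prediction metrics using only the first one or two biopsies per patient.

    One-biopsy metrics score each patient's first slide; two-biopsy metrics
    average the first and second slide probabilities, restricted to patients
    with at least two slides.
    """
    first_scores, first_labels = [], []
    two_scores, two_labels = [], []
    for s in streams:
        y = int(s.gene_truth.get(gene) == "mutant")
        first_scores.append(s.slides[0].probabilities[gene])
        first_labels.append(y)
        if len(s.slides) >= 2:
            two_scores.append(
                (s.slides[0].probabilities[gene] + s.slides[1].probabilities[gene]) / 2
            )
            two_labels.append(y)
    out = {
        "one_biopsy": ev.evaluate_task(
            first_scores, first_labels, task=f"{gene}@1", n_perm=n_perm, seed=seed
        )
    }
    if len(two_scores) >= 2 and len(set(two_labels)) == 2:
        out["two_biopsy"] = ev.evaluate_task(
            two_scores, two_labels, task=f"{gene}@2", n_perm=n_perm, seed=seed
        )
    else:
        warnings.warn("two-biopsy metrics omitted: insufficient multi-slide patients")
    return out
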