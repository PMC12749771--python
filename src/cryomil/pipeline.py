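"""End-to-end experiment orchestration.

Three analysis parts mirror the clinical validation design:

* Part I  — per-gene cross-validated prediction on Pass slides only.
* Part II — repurposing No-Pass slides: (a) transfer, where the Part-I fold
  models are applied to all No-Pass slides and their probabilities averaged
  (probability-level majority voting); (b) retrain, a fresh cross-validation
  on No-Pass slides alone.
* Part III — models trained on all slides feed the sequential re-biopsy
  re-checking simulation; a "consecutive" mode trains on the full primary
  cohort and scores a second cohort.

A dual-validation run applies the same machinery to the pilocytic-
astrocytoma label (5 folds, 8:2 split, Pass slides). Per-gene models are
fully independent runs. Every run can emit a manifest (config hash + seeds)
sufficient to reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import stats as ev
from .errors import ConfigurationError
from .model import MILHyperparams, MILModel, slide_logits, train_classifier
from .rebiopsy import (
    PatientStream,
    RebiopsyResult,
    StreamSlide,
    ai_biopsy_count,
    human_biopsy_count,
    summarize_counts,
)
from .synthetic import CohortConfig, FeatureBag, SlideRecord, generate_cohort

logger = logging.getLogger("cryomil")


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig
    tasks: tuple[str, ...] = ("ATRX", "H3K27M", "TP53")
    subset: str = "pass"  # pass | nopass | all
    cv_k: int = 10
    cv_seed: int = 0
    hyperparams: MILHyperparams = field(default_factory=MILHyperparams)
    n_perm: int = 1000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ConfigurationError("tasks must be non-empty")
        if self.subset not in ("pass", "nopass", "all"):
            raise ConfigurationError("subset must be pass|nopass|all")


def slide_label(record: SlideRecord, task: str) -> int:
    if task == "PA":
        return int(record.pa_label)
    if task not in record.gene_labels:
        raise ConfigurationError(f"no labels for task '{task}'")
    return int(record.gene_labels[task] == "mutant")


def subset_slides(
    records: list[SlideRecord], bags: list[FeatureBag], subset: str
) -> tuple[list[SlideRecord], list[FeatureBag]]:
    if subset == "all":
        return list(records), list(bags)
    want = "Pass" if subset == "pass" else "No-Pass"
    pairs = [(r, b) for r, b in zip(records, bags) if r.pass_status == want]
    return [r for r, _ in pairs], [b for _, b in pairs]


@dataclass
class CVResult:
    task: str
    report: ev.EvalReport
    fold_aucs: list[float]
    fold_models: list[MILModel]
    fold_thresholds: list[float]  # balanced threshold from each fold's training set
    slide_probs: dict[str, float]  # held-out P(mutant) per slide
    slide_fold: dict[str, int]
    plan: ev.FoldPlan


def cross_validate(
    records: list[SlideRecord],
    bags: list[FeatureBag],
    task: str,
    k: int,
    hyperparams: MILHyperparams,
    seed: int = 0,
    n_perm: int = 1000,
    ratio: str | None = None,
) -> CVResult:
    """Patient-level k-fold cross-validation for one prediction task."""
    plan = ev.make_folds(records, k, task, seed=seed, ratio=ratio)
    labels = np.array([slide_label(r, task) for r in records])
    probs: dict[str, float] = {}
    slide_fold: dict[str, int] = {}
    fold_aucs: list[float] = []
    fold_models: list[MILModel] = []
    fold_thresholds: list[float] = []
    for f, test_patients in enumerate(plan.folds):
        train_idx = [
            i for i, r in enumerate(records) if r.patient_id not in test_patients
        ]
        test_idx = [i for i, r in enumerate(records) if r.patient_id in test_patients]
        hp = dataclasses.replace(hyperparams, seed=hyperparams.seed + f)
        model = train_classifier(
            [bags[i] for i in train_idx], labels[train_idx], hp
        )
        fold_models.append(model)
        train_scores = [slide_logits(bags[i], model).p_mutant for i in train_idx]
        thr, _, _, _ = ev.balanced_threshold(train_scores, labels[train_idx])
        fold_thresholds.append(thr)
        test_scores = [slide_logits(bags[i], model).p_mutant for i in test_idx]
        for i, s in zip(test_idx, test_scores):
            probs[records[i].slide_id] = s
            slide_fold[records[i].slide_id] = f
        if len(set(labels[test_idx])) == 2:
            auc, _, _ = ev.roc_auc(test_scores, labels[test_idx])
            fold_aucs.append(auc)
        logger.info("task=%s fold=%d trained (%d slides)", task, f, len(train_idx))
    pooled_scores = np.array([probs[r.slide_id] for r in records])
    report = ev.evaluate_task(
        pooled_scores,
        labels,
        task=task,
        n_perm=n_perm,
        seed=seed,
        ci_method="fold-spread" if len(fold_aucs) >= 2 else "DeLong",
        fold_aucs=fold_aucs if len(fold_aucs) >= 2 else None,
    )
    return CVResult(
        task=task,
        report=report,
        fold_aucs=fold_aucs,
        fold_models=fold_models,
        fold_thresholds=fold_thresholds,
        slide_probs=probs,
        slide_fold=slide_fold,
        plan=plan,
    )


def _manifest(config: ExperimentConfig, part: str) -> dict:
    blob = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode()
    return {
        "part": part,
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "cohort_seed": config.cohort.seed,
        "cv_seed": config.cv_seed,
        "training_seed": config.hyperparams.seed,
    }


def _write_manifest(config: ExperimentConfig, manifest: dict) -> None:
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_part1(
    config: ExperimentConfig,
    records: list[SlideRecord] | None = None,
    bags: list[FeatureBag] | None = None,
) -> dict[str, CVResult]:
    """Per-gene cross-validation on Pass slides."""
    if records is None or bags is None:
        records, bags = generate_cohort(config.cohort)
    recs, bgs = subset_slides(records, bags, "pass")
    results = {
        task: cross_validate(
            recs, bgs, task, config.cv_k, config.hyperparams,
            seed=config.cv_seed, n_perm=config.n_perm,
        )
        for task in config.tasks
    }
    _write_manifest(config, _manifest(config, "part1"))
    return results


def run_part2(
    config: ExperimentConfig,
    part1: dict[str, CVResult] | None = None,
    records: list[SlideRecord] | None = None,
    bags: list[FeatureBag] | None = None,
    mode: str = "transfer",
) -> dict[str, ev.EvalReport | CVResult]:
    """No-Pass analysis: transfer the Pass fold models, or retrain from scratch."""
    if mode not in ("transfer", "retrain"):
        raise ConfigurationError("mode must be 'transfer' or 'retrain'")
    if records is None or bags is None:
        records, bags = generate_cohort(config.cohort)
    recs, bgs = subset_slides(records, bags, "nopass")
    out: dict[str, ev.EvalReport | CVResult] = {}
    if mode == "retrain":
        for task in config.tasks:
            out[task] = cross_validate(
                recs, bgs, task, config.cv_k, config.hyperparams,
                seed=config.cv_seed, n_perm=config.n_perm,
            )
        _write_manifest(config, _manifest(config, "part2-retrain"))
        return out
    if part1 is None:
        raise ConfigurationError("transfer mode requires Part-I fold models")
    for task in config.tasks:
        if task not in part1 or not part1[task].fold_models:
            raise ConfigurationError(f"no Part-I fold models for task '{task}'")
        matrix = [
            [slide_logits(b, m).p_mutant for b in bgs]
            for m in part1[task].fold_models
        ]
        voted = ev.ensemble_vote(matrix)
        labels = [slide_label(r, task) for r in recs]
        out[task] = ev.evaluate_task(
            voted, labels, task=task, n_perm=config.n_perm, seed=config.cv_seed
        )
    _write_manifest(config, _manifest(config, "part2-transfer"))
    return out


def build_streams(
    records: list[SlideRecord],
    probs_by_gene: dict[str, dict[str, float]],
    genes: tuple[str, ...],
    patient_subset: set[str] | None = None,
) -> list[PatientStream]:
    """Assemble per-patient ordered streams from per-slide probabilities."""
    by_patient: dict[str, list[SlideRecord]] = {}
    for r in records:
        if patient_subset is not None and r.patient_id not in patient_subset:
            continue
        by_patient.setdefault(r.patient_id, []).append(r)
    streams = []
    for pid, recs in sorted(by_patient.items()):
        recs = sorted(recs, key=lambda r: r.biopsy_order)
        streams.append(
            PatientStream(
                patient_id=pid,
                gene_truth={g: recs[0].gene_labels[g] for g in genes},
                slides=[
                    StreamSlide(
                        biopsy_order=r.biopsy_order,
                        pass_status=r.pass_status,
                        probabilities={
                            g: probs_by_gene[g][r.slide_id] for g in genes
                        },
                    )
                    for r in recs
                ],
            )
        )
    return streams


def run_part3(
    config: ExperimentConfig,
    records: list[SlideRecord] | None = None,
    bags: list[FeatureBag] | None = None,
    mode: str = "strict",
) -> tuple[RebiopsyResult, dict[str, CVResult]]:
    """Train per-gene models on all slides and replay the biopsy streams.

    Cross-validated so every slide is scored by a model that never saw its
    patient; each fold's decisions use that fold's training-set thresholds,
    and the per-fold counts are then combined.
    """
    if records is None or bags is None:
        records, bags = generate_cohort(config.cohort)
    cv_results = {
        task: cross_validate(
            records, bags, task, config.cv_k, config.hyperparams,
            seed=config.cv_seed, n_perm=0,
        )
        for task in config.tasks
    }
    probs_by_gene = {t: cv_results[t].slide_probs for t in config.tasks}
    human_all: list[int] = []
    ai_all: list[int] = []
    raw_all: list[int] = []
    pids: list[str] = []
    plan = cv_results[config.tasks[0]].plan
    for f, test_patients in enumerate(plan.folds):
        thresholds = {t: cv_results[t].fold_thresholds[f] for t in config.tasks}
        streams = build_streams(
            records, probs_by_gene, config.tasks, patient_subset=test_patients
        )
        for s in streams:
            human_all.append(human_biopsy_count(s))
            ai_all.append(ai_biopsy_count(s, thresholds, mode=mode))
            raw_all.append(ai_biopsy_count(s, thresholds, mode=mode, cap=False))
            pids.append(s.patient_id)
    result = summarize_counts(human_all, ai_all, raw_ai=raw_all, patient_ids=pids)
    _write_manifest(config, _manifest(config, "part3"))
    return result, cv_results


def run_part3_consecutive(
    config: ExperimentConfig,
    train_records: list[SlideRecord],
    train_bags: list[FeatureBag],
    test_records: list[SlideRecord],
    test_bags: list[FeatureBag],
    mode: str = "strict",
) -> RebiopsyResult:
    """Consecutive-style re-check: train on the full primary cohort, apply to
    a second cohort's streams; thresholds come from the training cohort."""
    probs_by_gene: dict[str, dict[str, float]] = {}
    thresholds: dict[str, float] = {}
    labels_cache = {}
    for task in config.tasks:
        labels = np.array([slide_label(r, task) for r in train_records])
        labels_cache[task] = labels
        model = train_classifier(train_bags, labels, config.hyperparams)
        train_scores = [slide_logits(b, model).p_mutant for b in train_bags]
        thr, _, _, _ = ev.balanced_threshold(train_scores, labels)
        thresholds[task] = thr
        probs_by_gene[task] = {
            r.slide_id: slide_logits(b, model).p_mutant
            for r, b in zip(test_records, test_bags)
        }
    streams = build_streams(test_records, probs_by_gene, config.tasks)
    human = [human_biopsy_count(s) for s in streams]
    ai = [ai_biopsy_count(s, thresholds, mode=mode) for s in streams]
    raw = [ai_biopsy_count(s, thresholds, mode=mode, cap=False) for s in streams]
    return summarize_counts(
        human, ai, raw_ai=raw, patient_ids=[s.patient_id for s in streams]
    )


def run_dual_validation(
    config: ExperimentConfig,
    records: list[SlideRecord] | None = None,
    bags: list[FeatureBag] | None = None,
) -> CVResult:
    """Pilocytic-astrocytoma identification: 5-fold, 8:2 split, Pass slides."""
    if records is None or bags is None:
        records, bags = generate_cohort(config.cohort)
    recs, bgs = subset_slides(records, bags, "pass")
    if not any(r.pa_label for r in recs):
        raise ConfigurationError("cohort carries no PA labels")
    return cross_validate(
        recs, bgs, "PA", 5, config.hyperparams,
        seed=config.cv_seed, n_perm=config.n_perm, ratio="8:2",
    )
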