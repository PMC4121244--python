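"""Train/test evaluation of the detector on simulated cohorts.

Mirrors the study protocol at desk scale: a set of annotated recordings is
split into a training half (classifier fitting) and a held-out test half
(scoring against annotations through the contingency table). Also reports the
stage-1 operating point — the fraction of annotated swallows recovered by the
EMG/BI coincidence filter alone, before any classification.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import ConfusionTable, match_events
from .io import EMBIRecording, EventAnnotation, PipelineConfig
from .pipeline import SwallowDetector
from .synthetic import CohortSpec, GroundTruth, generate_benchmark

__all__ = ["BenchmarkResult", "stage1_recall", "evaluate_split"]

Dataset = list[tuple[EMBIRecording, list[EventAnnotation], list[GroundTruth]]]


@dataclass(frozen=True)
class BenchmarkResult:
    """Held-out operating point of the two-stage detector on one cohort."""

    confusion: ConfusionTable
    stage1_recall: float  # over ALL recordings, before classification
    n_train_swallows: int
    n_test_swallows: int
    n_test_nonswallows: int

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float:
        return self.confusion.specificity

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy


def stage1_recall(detector: SwallowDetector, dataset: Dataset) -> float:
    """Fraction of annotated swallows with >= 1 coincidence candidate inside."""
    hit = 0
    total = 0
    for rec, events, _truths in dataset:
        cands = detector.stage1_candidates(rec)
        for ev in events:
            if ev.label != "swallow":
                continue
            total += 1
            if any(ev.contains(c.valley.t_min) for c in cands):
                hit += 1
    return hit / total if total else float("nan")


def evaluate_split(
    dataset: Dataset,
    n_train: int,
    config: PipelineConfig | None = None,
    random_state: int | None = 0,
) -> tuple[BenchmarkResult, SwallowDetector]:
    """Train on the first *n_train* recordings, score on the rest."""
    if not 0 < n_train < len(dataset):
        raise ValueError("n_train must split the dataset into two non-empty halves")
    train, test = dataset[:n_train], dataset[n_train:]
    det = SwallowDetector(config=config, random_state=random_state).fit(
        [rec for rec, _, _ in train], [ev for _, ev, _ in train]
    )
    table = ConfusionTable(0, 0, 0, 0)
    for rec, events, _ in test:
        table = table + match_events(det.predict(rec), events)
    result = BenchmarkResult(
        confusion=table,
        stage1_recall=stage1_recall(det, dataset),
        n_train_swallows=sum(
            1 for _, evs, _ in train for e in evs if e.label == "swallow"
        ),
        n_test_swallows=table.tp + table.fn,
        n_test_nonswallows=table.tn + table.fp,
    )
    return result, det


def run_cohort_benchmark(
    spec: CohortSpec,
    n_recordings: int = 40,
    seed: int | None = None,
    n_train: int | None = None,
    config: PipelineConfig | None = None,
) -> tuple[BenchmarkResult, SwallowDetector, Dataset]:
    """Generate a cohort, split it in half and evaluate the detector."""
    dataset = generate_benchmark(spec, n_recordings, seed=seed)
    if n_train is None:
        n_train = n_recordings // 2
    result, det = evaluate_split(dataset, n_train, config=config)
    return result, det, dataset
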