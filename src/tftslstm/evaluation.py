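"""Classification metrics and grouped, stratified k-fold cross-validation.

With condition positive P = TP + FN (disease records) and condition
negative N = TN + FP (control records):

    ACC = (TP + TN) / (P + N)        SEN = TP / P        SPE = TN / N
    PRE = TP / (TP + FP)             F1  = 2 TP / (2 TP + FP + FN)

Cross-validation operates on *source recordings*: every derived chunk and
balancing copy of a recording stays inside that recording's fold, so no
material leaks across the train/test boundary.  Balancing and feature
standardization are fitted inside each training split only.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EmbeddingConfig, TimeSeries
from .model import BiLSTMClassifier, BiLSTMResults, TrainConfig
from . import pipeline

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "confusion",
    "metrics",
    "cross_validate",
]

METRIC_NAMES = ("ACC", "SEN", "SPE", "PRE", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (disease is the positive class)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1, all in [0, 1]."""

    acc: float
    sen: float
    spe: float
    pre: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(METRIC_NAMES, (self.acc, self.sen, self.spe, self.pre, self.f1)))


def confusion(true_labels, predicted_labels, positive_label) -> ConfusionCounts:
    """Count TP/FP/TN/FN with ``positive_label`` as the disease class."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    labels = set(true_labels) | set(predicted_labels)
    if len(labels - {positive_label}) > 1:
        raise ValueError(f"expected binary labels, got {sorted(map(str, labels))}")
    tp = fp = tn = fn = 0
    for t, pr in zip(true_labels, predicted_labels):
        if t == positive_label:
            if pr == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if pr == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the five metrics from confusion counts.

    SEN (SPE) require at least one positive (negative) record; an undefined
    precision (TP + FP = 0) is reported as 0 with a warning so fold
    aggregation stays total.
    """
    if counts.total == 0:
        raise ValueError("no evaluated records")
    acc = (counts.tp + counts.tn) / counts.total
    sen = counts.tp / counts.p if counts.p > 0 else 0.0
    spe = counts.tn / counts.n if counts.n > 0 else 0.0
    if counts.tp + counts.fp == 0:
        warnings.warn("no positive predictions; precision reported as 0", RuntimeWarning)
        pre = 0.0
    else:
        pre = counts.tp / (counts.tp + counts.fp)
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / denom if denom > 0 else 0.0
    return MetricsReport(acc=acc, sen=sen, spe=spe, pre=pre, f1=f1)


@dataclass
class CVResult:
    """Per-fold metrics with mean and standard deviation, plus fold map."""

    folds: list[MetricsReport]
    fold_assignment: dict[str, int]  # source id -> fold index
    train_seconds: list[float]
    epoch_seconds: list[float]  # all per-epoch times pooled over folds
    training_logs: list[list[dict]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.folds)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.folds])

    def mean(self) -> dict[str, float]:
        return self.table().mean().to_dict()

    def sd(self) -> dict[str, float]:
        return self.table().std(ddof=1).to_dict()

    @property
    def mean_epoch_seconds(self) -> float:
        return float(np.mean(self.epoch_seconds))

    def summary(self) -> str:
        mean, sd = self.mean(), self.sd()
        head = f"{self.k}-fold cross-validation"
        cols = "  ".join(f"{m:>14s}" for m in METRIC_NAMES)
        vals = "  ".join(f"{mean[m]:7.4f}±{sd[m]:5.4f}" for m in METRIC_NAMES)
        total_time = sum(self.train_seconds)
        return "\n".join(
            [
                head,
                "=" * max(len(cols), len(head)),
                cols,
                vals,
                f"training time: {total_time / 60.0:.2f} min total, "
                f"{self.mean_epoch_seconds:.3f} s/epoch",
            ]
        )


def _stratified_group_folds(
    labels_by_source: dict[str, str], k: int, rng: np.random.Generator
) -> dict[str, int]:
    """Deal shuffled sources of each class round-robin over k folds."""
    assignment: dict[str, int] = {}
    by_class: dict[str, list[str]] = {}
    for sid, label in labels_by_source.items():
        by_class.setdefault(label, []).append(sid)
    for label, sids in sorted(by_class.items()):
        if len(sids) < k:
            raise ValueError(f"class {label!r} has {len(sids)} source records; need >= k={k}")
        sids = sorted(sids)
        rng.shuffle(sids)
        for pos, sid in enumerate(sids):
            assignment[sid] = pos % k
    return assignment


def cross_validate(
    records: list[TimeSeries],
    k: int = 10,
    config: TrainConfig | None = None,
    seed: int = 0,
    positive_label: str | None = None,
    segment_length: int = pipeline.DEFAULT_SEGMENT_LENGTH,
    embedding: EmbeddingConfig = EmbeddingConfig(1, 1),
    n_clusters: int = 3,
    representation: str = "features",
    balance: bool = True,
    equalize: bool = True,
) -> CVResult:
    """Full stratified grouped k-fold experiment over raw records.

    The records are length-equalized once, transformed to sequences once
    (``representation="features"`` for the M x 4 feature sequences,
    ``"raw"`` for L x 1 raw-signal sequences), then folds are formed over
    source recordings.  Per fold the training split is class-balanced, a
    standardizer is fitted on it, a model is trained and the untouched test
    fold is scored.
    """
    if representation not in ("features", "raw"):
        raise ValueError("representation must be 'features' or 'raw'")
    config = config or TrainConfig()
    prepared = (
        pipeline.equalize_lengths(records)
        if equalize
        else pipeline.PreparedDataset(records=list(records))
    )
    if positive_label is None:
        positive_label = sorted({r.label for r in prepared.records})[-1]

    if representation == "features":
        sequences = [
            pipeline.extract_features(
                r,
                segment_length=segment_length,
                embedding=embedding,
                n_clusters=n_clusters,
                seed=seed,
            )
            for r in prepared.records
        ]
    else:
        sequences = [pipeline.raw_sequence(r) for r in prepared.records]
    seq_by_id = {s.id: s for s in sequences}

    labels_by_source: dict[str, str] = {}
    for rec in prepared.records:
        labels_by_source[rec.source_id] = rec.label
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xF01D,)))
    assignment = _stratified_group_folds(labels_by_source, k, rng)

    folds: list[MetricsReport] = []
    train_seconds: list[float] = []
    epoch_seconds: list[float] = []
    logs: list[list[dict]] = []
    for fold in range(k):
        train_recs = [r for r in prepared.records if assignment[r.source_id] != fold]
        test_recs = [r for r in prepared.records if assignment[r.source_id] == fold]
        if balance:
            train_recs = pipeline.balance_classes(
                pipeline.PreparedDataset(records=train_recs)
            ).records
        # balancing copies reuse their source record's precomputed sequence
        train_seqs = [
            pipeline.FeatureSequence(
                id=r.id,
                features=seq_by_id[r.id.split("~")[0]].features,
                label=r.label,
                source_id=r.source_id,
            )
            for r in train_recs
        ]
        std = pipeline.fit_standardizer(train_seqs)
        train_seqs = [pipeline.apply_standardizer(std, s) for s in train_seqs]
        test_seqs = [pipeline.apply_standardizer(std, seq_by_id[r.id]) for r in test_recs]

        fold_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(1, fold)).generate_state(1)[0])
        t0 = time.perf_counter()
        res = BiLSTMClassifier(train_seqs, config=config, standardizer=std).fit(seed=fold_seed)
        train_seconds.append(time.perf_counter() - t0)
        epoch_seconds.extend(e["epoch_seconds"] for e in res.training_log)
        logs.append(res.training_log)

        preds = [lbl for lbl, _ in res.predict(test_seqs)]
        truth = [r.label for r in test_recs]
        folds.append(metrics(confusion(truth, preds, positive_label)))
    return CVResult(
        folds=folds,
        fold_assignment=assignment,
        train_seconds=train_seconds,
        epoch_seconds=epoch_seconds,
        training_logs=logs,
    )
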