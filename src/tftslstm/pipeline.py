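"""Data preparation and feature-sequence assembly.

Raw recordings rarely share a length, and disease classes are usually the
minority.  Preparation therefore proceeds in two steps:

1. *Length equalization* — the modal ("majority") record length is found
   from the length histogram; shorter records are discarded and longer ones
   are split into consecutive chunks of the modal length (the remainder is
   dropped).
2. *Class balancing* — minority-class records are repeated cyclically in
   their original order until class counts match.

Every equal-length record is then transformed into a feature sequence: it
is split into M = ceil(L / N) consecutive segments (N = 128 samples by
default; the last segment may be shorter), and each segment yields four
scalar features — instantaneous frequency, spectral entropy, fuzzy
recurrence image entropy and fuzzy recurrence entropy.  The M x 4 matrix
replaces the raw signal as classifier input.  Features are z-scored with
statistics pooled over the training segments only.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EmbeddingConfig, TimeSeries
from . import timefreq, timespace

__all__ = [
    "PreparedDataset",
    "FeatureSequence",
    "StandardizationParams",
    "equalize_lengths",
    "balance_classes",
    "extract_features",
    "raw_sequence",
    "fit_standardizer",
    "apply_standardizer",
    "feature_frame",
]

DEFAULT_SEGMENT_LENGTH = 128
FEATURE_NAMES = ("if_hz", "spectral_entropy", "frp_image_entropy", "fuzzy_recurrence_entropy")


@dataclass
class PreparedDataset:
    """Equal-length records plus a provenance map derived-id -> source-id."""

    records: list[TimeSeries]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> Counter:
        return Counter(r.label for r in self.records)


@dataclass
class FeatureSequence:
    """M x Q feature matrix for one record (rows are segments)."""

    id: str
    features: np.ndarray  # (M, Q)
    label: str | None = None
    source_id: str | None = None
    raw_fuzzy_recurrence_entropy: np.ndarray | None = None  # un-normalized E_FR per segment

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be an M x Q matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"feature sequence {self.id!r} contains non-finite values")
        if self.source_id is None:
            self.source_id = self.id

    @property
    def n_segments(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature mean and standard deviation fitted on training segments."""

    mean: np.ndarray
    sd: np.ndarray


def equalize_lengths(records: list[TimeSeries], prefer_longer_tie: bool = True) -> PreparedDataset:
    """Cut every record to the majority (modal) length.

    Records shorter than the mode are discarded; longer records contribute
    floor(L / mode) derived chunks (ids ``"<id>#<k>"``) with the remainder
    ignored.  A tie between modal lengths is broken toward the longer
    length by default, retaining more signal.
    """
    if not records:
        raise ValueError("cannot equalize an empty record list")
    counts = Counter(len(r) for r in records)
    top = max(counts.values())
    candidates = [length for length, cnt in counts.items() if cnt == top]
    mode = max(candidates) if prefer_longer_tie else min(candidates)

    out: list[TimeSeries] = []
    provenance: dict[str, str] = {}
    for rec in records:
        n_chunks = len(rec) // mode
        if n_chunks == 0:
            continue  # shorter than the majority: discarded
        if n_chunks == 1 and len(rec) == mode:
            out.append(rec)
            provenance[rec.id] = rec.source_id
            continue
        for k in range(n_chunks):
            chunk_id = f"{rec.id}#{k}"
            out.append(
                TimeSeries(
                    id=chunk_id,
                    samples=rec.samples[k * mode : (k + 1) * mode],
                    fs=rec.fs,
                    label=rec.label,
                    source_id=rec.source_id,
                )
            )
            provenance[chunk_id] = rec.source_id
    return PreparedDataset(records=out, provenance=provenance)


def balance_classes(dataset: PreparedDataset | list[TimeSeries]) -> PreparedDataset:
    """Repeat minority-class records cyclically until class counts match.

    Copies keep their source record's ``source_id`` and get ids
    ``"<id>~<n>"``; every original record is preserved.
    """
    if isinstance(dataset, PreparedDataset):
        records, provenance = list(dataset.records), dict(dataset.provenance)
    else:
        records, provenance = list(dataset), {}
    by_class: dict[str, list[TimeSeries]] = {}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} has no class label")
        by_class.setdefault(rec.label, []).append(rec)
    if len(by_class) < 2:
        raise ValueError("balancing requires at least two classes")
    target = max(len(v) for v in by_class.values())
    out = list(records)
    for label, members in sorted(by_class.items()):
        deficit = target - len(members)
        for n in range(deficit):
            src = members[n % len(members)]
            copy_id = f"{src.id}~{n // len(members) + 1}"
            out.append(
                TimeSeries(
                    id=copy_id,
                    samples=src.samples,
                    fs=src.fs,
                    label=src.label,
                    source_id=src.source_id,
                )
            )
            provenance[copy_id] = src.source_id
    return PreparedDataset(records=out, provenance=provenance)


def _segment_features(
    seg: np.ndarray,
    fs: float,
    embedding: EmbeddingConfig,
    n_clusters: int,
    beta: float,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Four features of one segment; returns (row, raw E_FR)."""
    if seg.size < n_clusters + 1:
        warnings.warn(
            f"segment of {seg.size} samples too short for c={n_clusters} clusters; "
            "features set to zero",
            RuntimeWarning,
        )
        return np.zeros(4), 0.0
    if np.ptp(seg) == 0:
        # constant segment: degenerate spectrum and a single phase-space point
        # repeated; every feature collapses to its limit value
        return np.zeros(4), 0.0
    ps = timefreq.power_spectrum(seg, fs=fs, beta=beta)
    f_if = timefreq.instantaneous_frequency(ps)
    f_se = timefreq.spectral_entropy(ps)
    pss = timespace.embed(seg, embedding)
    fcm = timespace.fuzzy_c_means(pss, c=n_clusters, seed=seed)
    frp = timespace.fuzzy_recurrence_plot(fcm)
    f_fri = timespace.frp_image_entropy(frp)
    raw_fr = timespace.fuzzy_recurrence_entropy(frp)
    n = frp.shape[0]
    return np.array([f_if, f_se, f_fri, raw_fr / n**2]), raw_fr


def extract_features(
    record: TimeSeries,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    embedding: EmbeddingConfig = EmbeddingConfig(1, 1),
    n_clusters: int = 3,
    seed: int = 0,
    beta: float = timefreq.DEFAULT_KAISER_BETA,
) -> FeatureSequence:
    """Transform a record into its M x 4 feature sequence.

    M = ceil(L / segment_length); the last segment may be shorter and is
    used as-is when it has enough samples to cluster.  The fuzzy recurrence
    entropy column is divided by its segment's N^2 (its maximum) so partial
    segments stay on a common scale; the raw values are retained alongside.
    Fuzzy c-means is sub-seeded per segment index from ``seed``, so features
    are reproducible and independent of record order.
    """
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    x = record.samples
    m = int(np.ceil(len(x) / segment_length))
    rows = np.empty((m, 4))
    raw_fr = np.empty(m)
    for tau in range(m):
        seg = x[tau * segment_length : (tau + 1) * segment_length]
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(tau,))
        sub_seed = int(ss.generate_state(1)[0])
        rows[tau], raw_fr[tau] = _segment_features(
            seg, record.fs, embedding, n_clusters, beta, sub_seed
        )
    return FeatureSequence(
        id=record.id,
        features=rows,
        label=record.label,
        source_id=record.source_id,
        raw_fuzzy_recurrence_entropy=raw_fr,
    )


def raw_sequence(record: TimeSeries) -> FeatureSequence:
    """Wrap a raw signal as an L x 1 sequence (the conventional-LSTM input)."""
    return FeatureSequence(
        id=record.id,
        features=record.samples[:, None],
        label=record.label,
        source_id=record.source_id,
    )


def fit_standardizer(train: list[FeatureSequence]) -> StandardizationParams:
    """Per-feature mean/sd pooled over every training segment.

    A zero-variance feature keeps sd = 1 (with a warning) so its z-scores
    are zero rather than undefined.
    """
    if not train:
        raise ValueError("cannot fit a standardizer on an empty training set")
    stacked = np.vstack([fs.features for fs in train])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance feature column(s); sd replaced by 1", RuntimeWarning)
        sd = np.where(sd == 0, 1.0, sd)
    return StandardizationParams(mean=mean, sd=sd)


def apply_standardizer(params: StandardizationParams, seq: FeatureSequence) -> FeatureSequence:
    """z-score a feature sequence with (training) statistics in ``params``."""
    return FeatureSequence(
        id=seq.id,
        features=(seq.features - params.mean) / params.sd,
        label=seq.label,
        source_id=seq.source_id,
        raw_fuzzy_recurrence_entropy=seq.raw_fuzzy_recurrence_entropy,
    )


def feature_frame(sequences: list[FeatureSequence]) -> pd.DataFrame:
    """Long-format DataFrame (id, segment, four features, label) for CSV export."""
    rows = []
    for fs in sequences:
        for tau, row in enumerate(fs.features):
            names = (
                FEATURE_NAMES
                if fs.features.shape[1] == len(FEATURE_NAMES)
                else [f"f{i}" for i in range(fs.features.shape[1])]
            )
            rows.append(
                {"id": fs.id, "segment": tau, **dict(zip(names, row)), "label": fs.label}
            )
    return pd.DataFrame(rows)
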