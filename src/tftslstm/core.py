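"""Core domain containers shared across the package.

A :class:`TimeSeries` is the unit of data everywhere: a finite univariate
signal with a sampling frequency and an optional class label.  Derived
records (length-equalized chunks, balancing copies) carry a ``source_id``
pointing back at the original recording so that cross-validation can keep
all material from one recording inside one fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "EmbeddingConfig"]


@dataclass
class TimeSeries:
    """A univariate, uniformly sampled real-valued signal.

    Parameters
    ----------
    id : str
        Unique record identifier.
    samples : array_like
        Finite real samples, length >= 1.
    fs : float
        Sampling frequency in Hz, > 0.
    label : str, optional
        Class label ("chaotic", "AF", ...), if known.
    source_id : str, optional
        Identifier of the source recording this record was derived from.
        Defaults to ``id`` for primary records.
    """

    id: str
    samples: np.ndarray
    fs: float
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError(f"record {self.id!r}: samples must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.id!r}: samples contain non-finite values")
        if not (self.fs > 0):
            raise ValueError(f"record {self.id!r}: sampling frequency must be > 0, got {self.fs}")
        if self.source_id is None:
            self.source_id = self.id

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class EmbeddingConfig:
    """Time-delay embedding parameters: dimension ``d`` and delay (lag) ``phi``."""

    dimension: int = 1
    delay: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.dimension, (int, np.integer)) and self.dimension >= 1):
            raise ValueError("embedding dimension must be an integer >= 1")
        if not (isinstance(self.delay, (int, np.integer)) and self.delay >= 1):
            raise ValueError("embedding delay must be an integer >= 1")
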