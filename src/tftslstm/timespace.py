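"""Time-space features: embedding, fuzzy c-means, fuzzy recurrence plots, entropies.

A scalar series is lifted into phase space by time-delay embedding, the
phase-space vectors are soft-partitioned into ``c`` clusters with fuzzy
c-means (FCM), and a fuzzy recurrence plot (FRP) is inferred from the
membership matrix by the three fuzzy-relation properties:

* reflexivity   mu(x_i, x_i) = 1,
* symmetry      mu(x_i, v_q) = mu(v_q, x_i),
* transitivity  mu(x_i, x_j) = max_q min{mu(x_i, v_q), mu(x_j, v_q)}.

The FRP is an N x N grayscale image with entries in [0, 1].  Two entropies
summarize it: the Shannon entropy of its 256-level gray histogram (image
entropy, in [0, 8] bits) and the De Luca-Termini fuzzy-set entropy summed
over all cells (fuzzy recurrence entropy, in [0, N^2] bits).  A binary
recurrence plot (distance threshold) is provided for comparison displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import EmbeddingConfig

__all__ = [
    "PhaseSpaceSet",
    "FCMResult",
    "embed",
    "fuzzy_c_means",
    "fuzzy_recurrence_plot",
    "recurrence_plot",
    "frp_image_entropy",
    "fuzzy_recurrence_entropy",
    "frp_to_image",
]


@dataclass(frozen=True)
class PhaseSpaceSet:
    """N phase-space vectors of dimension d, rows of ``vectors``."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("phase-space set must be a non-empty 2-d array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("phase-space vectors must be finite")

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class FCMResult:
    """Fuzzy c-means output: cluster centers, membership matrix, diagnostics."""

    centers: np.ndarray  # (c, d)
    memberships: np.ndarray  # (N, c), rows sum to 1
    n_iter: int
    objective: float
    objective_history: np.ndarray


def embed(x: np.ndarray, config: EmbeddingConfig = EmbeddingConfig(1, 1)) -> PhaseSpaceSet:
    """Time-delay embedding: vector i is (z_i, z_{i+phi}, ..., z_{i+(d-1)phi}).

    Produces N = I - (d-1)*phi vectors.  With d=1, phi=1 the vectors are the
    scalar samples themselves.
    """
    x = np.asarray(x, dtype=float)
    d, phi = config.dimension, config.delay
    need = (d - 1) * phi + 1
    if x.size < need:
        raise ValueError(
            f"series of length {x.size} too short for d={d}, delay={phi}; need at least {need}"
        )
    n = x.size - (d - 1) * phi
    vecs = np.column_stack([x[k * phi : k * phi + n] for k in range(d)])
    return PhaseSpaceSet(vectors=vecs)


def fuzzy_c_means(
    X: PhaseSpaceSet | np.ndarray,
    c: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> FCMResult:
    """Bezdek's fuzzy c-means on the rows of ``X``.

    Memberships are initialized from a seeded uniform sampler and
    row-normalized; centers and memberships then alternate until the
    objective J = sum_i sum_q u_iq^m ||x_i - v_q||^2 changes by less than
    ``tol`` or ``max_iter`` is reached.  A point coinciding with a center
    receives crisp membership for that center (avoids division by zero).
    """
    pts = X.vectors if isinstance(X, PhaseSpaceSet) else np.asarray(X, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if c < 2:
        raise ValueError("number of clusters c must be >= 2")
    if n < c:
        raise ValueError(f"need at least c={c} points, got {n}")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n, c))
    u /= u.sum(axis=1, keepdims=True)

    expo = 1.0 / (fuzzifier - 1.0)
    history: list[float] = []
    prev_obj = np.inf
    centers = np.zeros((c, pts.shape[1]))
    it = 0
    for it in range(1, max_iter + 1):
        um = u**fuzzifier
        centers = (um.T @ pts) / um.sum(axis=0)[:, None]
        d2 = cdist(pts, centers, metric="sqeuclidean")
        zero_rows = d2.min(axis=1) < 1e-24
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        if np.any(zero_rows):
            u[zero_rows] = 0.0
            u[zero_rows, d2[zero_rows].argmin(axis=1)] = 1.0
        obj = float(np.sum((u**fuzzifier) * d2))
        history.append(obj)
        if abs(prev_obj - obj) < tol:
            break
        prev_obj = obj
    return FCMResult(
        centers=centers,
        memberships=u,
        n_iter=it,
        objective=history[-1],
        objective_history=np.asarray(history),
    )


def fuzzy_recurrence_plot(fcm: FCMResult) -> np.ndarray:
    """FRP from an FCM membership matrix via max-min transitivity.

    R(i, j) = max_q min(u_iq, u_jq) for i != j; the diagonal is set to 1 by
    reflexivity.  The result is symmetric with entries in [0, 1].
    """
    u = fcm.memberships
    # max-min composition; N x N x c is small (N <= segment length)
    r = np.minimum(u[:, None, :], u[None, :, :]).max(axis=-1)
    np.fill_diagonal(r, 1.0)
    return r


def recurrence_plot(X: PhaseSpaceSet | np.ndarray, epsilon: float) -> np.ndarray:
    """Binary recurrence plot: 1 where the pair distance is <= epsilon."""
    pts = X.vectors if isinstance(X, PhaseSpaceSet) else np.asarray(X, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    d = cdist(pts, pts)
    return (d <= epsilon).astype(np.uint8)


def _quantize(r: np.ndarray) -> np.ndarray:
    """Map [0, 1] reals to integer gray levels 0..255, round half away from zero."""
    return np.floor(255.0 * r + 0.5).astype(np.int64)


def frp_image_entropy(r: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-level gray histogram of an FRP.

    Every matrix cell, including the unit diagonal, contributes to the
    histogram.  Range [0, 8] bits.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("FRP entries must lie in [0, 1]")
    counts = np.bincount(_quantize(r).ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def fuzzy_recurrence_entropy(r: np.ndarray) -> float:
    """De Luca-Termini fuzzy entropy summed over all FRP cells (bits).

    E = sum_ij [-mu log2 mu - (1-mu) log2(1-mu)], with the 0*log0 := 0
    limit, so crisp matrices give 0 and the all-0.5 matrix gives N^2.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("FRP entries must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, -r * np.log2(np.where(r > 0, r, 1.0)), 0.0)
        q = 1.0 - r
        t2 = np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
    return float(np.sum(t1 + t2))


def frp_to_image(r: np.ndarray, path: str) -> None:
    """Write an FRP (or binary RP) as an 8-bit grayscale PNG/PGM image.

    Convention follows recurrence-plot figures: membership 1 is black.
    """
    from PIL import Image

    gray = 255 - _quantize(np.asarray(r, dtype=float))
    Image.fromarray(gray.astype(np.uint8), mode="L").save(path)
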