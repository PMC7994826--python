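"""Synthetic labeled datasets with known dynamical structure.

Three generators cover the qualitative regimes relevant to physiological
signal classification: a chaotic deterministic flow (the X-component of the
Lorenz system), narrow-band oscillation (noisy sinusoid), and white noise.
``make_labeled_dataset`` assembles reproducible two-class datasets from
them, with every record sub-seeded from a single master seed so that
datasets are reproducible record-by-record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import TimeSeries

__all__ = [
    "lorenz_series",
    "sine_series",
    "white_noise_series",
    "DatasetSpec",
    "make_labeled_dataset",
]

#: Canonical chaotic parameter set for the Lorenz flow.
LORENZ_SIGMA = 10.0
LORENZ_RHO = 28.0
LORENZ_BETA = 8.0 / 3.0


def _lorenz_rhs(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def lorenz_series(
    n_points: int,
    dt: float = 0.01,
    init: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sigma: float = LORENZ_SIGMA,
    rho: float = LORENZ_RHO,
    beta: float = LORENZ_BETA,
    transient: int = 1000,
    fs: float = 300.0,
    id: str = "lorenz",
    label: str | None = None,
) -> TimeSeries:
    """X-component of the Lorenz system integrated with fixed-step RK4.

    The first ``transient`` steps after ``init`` are discarded so that the
    returned trajectory lies on the attractor.  With ``transient=0`` the
    first output sample is exactly the X-coordinate of ``init``.
    Deterministic for fixed inputs.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state = np.asarray(init, dtype=float)
    if state.shape != (3,):
        raise ValueError("init must be a 3-vector")
    out = np.empty(n_points)
    total = transient + n_points
    k = 0
    for step in range(total):
        if step >= transient:
            out[k] = state[0]
            k += 1
            if k == n_points:
                break
        k1 = _lorenz_rhs(state, sigma, rho, beta)
        k2 = _lorenz_rhs(state + 0.5 * dt * k1, sigma, rho, beta)
        k3 = _lorenz_rhs(state + 0.5 * dt * k2, sigma, rho, beta)
        k4 = _lorenz_rhs(state + dt * k3, sigma, rho, beta)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("Lorenz integration blew up (non-finite state)")
    return TimeSeries(id=id, samples=out, fs=fs, label=label)


def sine_series(
    f0: float,
    fs: float,
    n_points: int,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    id: str = "sine",
    label: str | None = None,
) -> TimeSeries:
    """Sinusoid ``amplitude*sin(2*pi*f0*k/fs)`` plus Gaussian noise.

    Raises if ``f0 >= fs/2`` (the tone would alias).  Reproducible under a
    fixed seed.
    """
    if not (0 < f0 < fs / 2):
        raise ValueError(f"f0 must satisfy 0 < f0 < fs/2 to avoid aliasing; got f0={f0}, fs={fs}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    k = np.arange(n_points)
    x = amplitude * np.sin(2 * np.pi * f0 * k / fs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n_points)
    return TimeSeries(id=id, samples=x, fs=fs, label=label)


def white_noise_series(
    fs: float,
    n_points: int,
    sd: float = 1.0,
    seed: int = 0,
    id: str = "noise",
    label: str | None = None,
) -> TimeSeries:
    """Gaussian white noise record."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    return TimeSeries(id=id, samples=rng.normal(0.0, sd, size=n_points), fs=fs, label=label)


# Generator registry: name -> callable(rng, n_points, fs, sub_seed, **params)
def _gen_sine(rng: np.random.Generator, n_points: int, fs: float, sub_seed: int, **params: Any):
    f0_range = params.pop("f0_range", (8.0, 12.0))
    f0 = params.pop("f0", None)
    if f0 is None:
        f0 = rng.uniform(*f0_range)
    params.setdefault("amplitude", 1.0)
    params.setdefault("noise_sd", 0.2)
    return sine_series(f0=f0, fs=fs, n_points=n_points, seed=sub_seed, **params)


def _gen_lorenz(rng: np.random.Generator, n_points: int, fs: float, sub_seed: int, **params: Any):
    # Random initial condition in a box around the attractor; the transient
    # relaxes it onto the attractor so records are diverse but on-manifold.
    init = params.pop(
        "init",
        (rng.uniform(-15, 15), rng.uniform(-20, 20), rng.uniform(5, 45)),
    )
    params.setdefault("transient", 1000)
    return lorenz_series(n_points=n_points, init=init, fs=fs, **params)


def _gen_white_noise(rng: np.random.Generator, n_points: int, fs: float, sub_seed: int, **params: Any):
    return white_noise_series(fs=fs, n_points=n_points, seed=sub_seed, **params)


_GENERATORS = {
    "sine": _gen_sine,
    "lorenz": _gen_lorenz,
    "chaotic": _gen_lorenz,
    "white_noise": _gen_white_noise,
}


@dataclass
class DatasetSpec:
    """Recipe for a labeled synthetic dataset.

    ``classes`` maps a class label to a dict with at least a ``"generator"``
    key (one of {sine, lorenz/chaotic, white_noise}); remaining keys are
    passed to the generator.
    """

    classes: dict[str, dict[str, Any]]
    n_per_class: int = 10
    length: int = 1280
    fs: float = 300.0
    seed: int = 0
    normalize: bool = True  # z-score each record so classes differ by dynamics, not scale

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for name, params in self.classes.items():
            gen = params.get("generator")
            if gen not in _GENERATORS:
                raise ValueError(
                    f"class {name!r}: unknown generator {gen!r}; expected one of {sorted(_GENERATORS)}"
                )


def default_dataset_spec(n_per_class: int = 100, length: int = 1280, seed: int = 0) -> DatasetSpec:
    """Two-class benchmark recipe: noisy sinusoids vs Lorenz-derived records."""
    return DatasetSpec(
        classes={
            "sine": {"generator": "sine", "f0_range": (8.0, 12.0), "noise_sd": 0.2},
            "chaotic": {"generator": "lorenz"},
        },
        n_per_class=n_per_class,
        length=length,
        seed=seed,
    )


def make_labeled_dataset(spec: DatasetSpec) -> list[TimeSeries]:
    """Generate the dataset described by ``spec``.

    Each record gets its own sub-seed derived from the master seed, class
    index and record index, so two runs with the same spec are
    byte-identical and removing one class does not perturb another.
    """
    records: list[TimeSeries] = []
    for ci, (label, params) in enumerate(sorted(spec.classes.items())):
        params = dict(params)
        gen = _GENERATORS[params.pop("generator")]
        for ri in range(spec.n_per_class):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(ci, ri))
            sub_seed = int(ss.generate_state(1)[0])
            rng = np.random.default_rng(sub_seed)
            rec = gen(rng, spec.length, spec.fs, sub_seed, **dict(params))
            samples = rec.samples
            if spec.normalize:
                sd = samples.std()
                samples = (samples - samples.mean()) / (sd if sd > 0 else 1.0)
            records.append(
                TimeSeries(id=f"{label}-{ri:04d}", samples=samples, fs=spec.fs, label=label)
            )
    return records
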