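"""Time-frequency features: windowed periodogram, spectral centroid, spectral entropy.

The power spectrum of a segment x_k, k = 0..N-1 is the scaled, windowed
periodogram

    P_j = (1 / (W N)) |sum_k w_k x_k exp(-i 2 pi j k / N)|^2,
    W   = (1/N) sum_j w_j^2,

computed with the FFT after zero-padding the segment to the next power of
two, with a Kaiser taper applied before the FFT.  Only the one-sided bins
j = 0..N/2 (frequencies in [0, fs/2]) are kept.  Two scalar features reduce
each segment's spectrum:

* instantaneous frequency — the power-weighted mean frequency (spectral
  centroid), in Hz;
* spectral entropy — the Shannon entropy (bits) of the normalized power
  distribution.

Both are invariant to positive rescaling of the signal, which is why the
one-sided spectrum is used without the interior-bin energy doubling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import kaiser as _scipy_kaiser

__all__ = [
    "WindowSpec",
    "PowerSpectrum",
    "kaiser_window",
    "next_pow2",
    "power_spectrum",
    "instantaneous_frequency",
    "spectral_entropy",
]

#: Default Kaiser shape parameter (near-rectangular taper).
DEFAULT_KAISER_BETA = 0.5


@dataclass(frozen=True)
class WindowSpec:
    """Window coefficients w_j plus their mean-square scale W."""

    coefficients: np.ndarray

    @property
    def scale(self) -> float:
        """W = (1/n) sum w_j^2."""
        w = self.coefficients
        return float(np.mean(w * w))

    def __len__(self) -> int:
        return self.coefficients.size


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power estimates P_j on the grid f_j = j*fs/nfft, j = 0..nfft/2."""

    frequencies: np.ndarray
    powers: np.ndarray
    fs: float
    nfft: int

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.powers.shape:
            raise ValueError("frequencies and powers must have the same shape")
        if np.any(self.powers < 0):
            raise ValueError("powers must be non-negative")


def kaiser_window(length: int, beta: float = DEFAULT_KAISER_BETA) -> WindowSpec:
    """Symmetric Kaiser window of a given length.

    ``beta=0`` degenerates to the rectangular window (all ones, W = 1).
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return WindowSpec(coefficients=_scipy_kaiser(length, beta, sym=True))


def next_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1 << (int(n) - 1).bit_length()


def power_spectrum(
    x: np.ndarray,
    fs: float,
    window: WindowSpec | None = None,
    beta: float = DEFAULT_KAISER_BETA,
) -> PowerSpectrum:
    """Windowed one-sided periodogram of a segment.

    The segment is zero-padded to ``nfft = next_pow2(len(x))``; the window is
    built (or must be supplied) at that padded length, so the taper weights
    the real samples and leaves the zero padding at zero.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-d sequence")
    nfft = next_pow2(x.size)
    if window is None:
        window = kaiser_window(nfft, beta)
    w = np.asarray(window.coefficients, dtype=float)
    if w.size != nfft:
        raise ValueError(f"window length {w.size} must equal padded length {nfft}")
    W = window.scale
    if W == 0:
        raise ZeroDivisionError("all-zero window has zero scale W")
    xp = np.zeros(nfft)
    xp[: x.size] = x
    spec = np.fft.rfft(w * xp)
    powers = (spec.real**2 + spec.imag**2) / (W * nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(frequencies=freqs, powers=powers, fs=fs, nfft=nfft)


def instantaneous_frequency(ps: PowerSpectrum) -> float:
    """Spectral centroid sum_j f_j P_j / sum_j P_j over [0, fs/2], in Hz.

    A segment with zero total power has no defined centroid; 0 Hz is
    returned with a warning so downstream feature matrices stay finite.
    """
    total = ps.powers.sum()
    if total <= 0:
        warnings.warn("zero total power; instantaneous frequency set to 0", RuntimeWarning)
        return 0.0
    return float(np.dot(ps.frequencies, ps.powers) / total)


def spectral_entropy(ps: PowerSpectrum) -> float:
    """Shannon entropy (bits) of the normalized power distribution.

    0 for a single occupied bin; log2(B) for a flat spectrum over B bins.
    Zero-power spectra return 0 with a warning.
    """
    total = ps.powers.sum()
    if total <= 0:
        warnings.warn("zero total power; spectral entropy set to 0", RuntimeWarning)
        return 0.0
    p = ps.powers / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))
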