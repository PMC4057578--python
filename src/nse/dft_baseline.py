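"""Radix-2 DFT baseline and spectral-resolution calculators.

The comparison baseline is a power-of-two FFT magnitude spectrum,
deliberately recomputed in full for every sliding-window position (move
size M >= 1) — the conventional real-time approach the ensemble estimator
is measured against.  Only spectral shape is compared across estimators,
so the magnitude convention (|X_k| / N) is fixed internally and documented
rather than matched to any particular scaling of the ensemble spectrum.

Resolution bookkeeping: a DFT over an N-sample window has uniform bin
spacing rate/N, while the period-domain grid has a local spacing of
``rate/w - rate/(w+1) ~ rate/w^2`` that is finest at low frequencies; the
mean of ``rate/w^2`` over the grid summarizes it as a single figure.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core import PeriodGrid, Signal
from .errors import RadixError

__all__ = [
    "DftSpectrum",
    "dft_power_spectrum",
    "sliding_dft",
    "dft_resolution",
    "nse_mean_resolution",
    "band_bin_count",
]


@dataclasses.dataclass(frozen=True)
class DftSpectrum:
    """Magnitude spectrum on the uniform bin grid ``k * rate / N``."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    N: int
    rate: float

    def __post_init__(self):
        if self.N < 2 or self.N & (self.N - 1):
            raise RadixError(f"window length {self.N} is not a power of two")

    def __len__(self) -> int:
        return self.magnitudes.size


def dft_power_spectrum(x: Signal, N: int) -> DftSpectrum:
    """Magnitude spectrum of the most recent ``N`` samples.

    ``N`` must be a power of two (radix-2).  Magnitudes are ``|X_k| / N``
    for the one-sided (real-input) transform; bins run from DC to Nyquist
    with spacing ``rate / N`` exactly.
    """
    if N < 2 or N & (N - 1):
        raise RadixError(f"window length {N} is not a power of two")
    xs = x.samples
    if xs.size < N:
        raise ValueError(f"signal length {xs.size} shorter than window {N}")
    window = xs[-N:]
    mags = np.abs(np.fft.rfft(window)) / N
    freqs = np.fft.rfftfreq(N, d=1.0 / x.rate)
    return DftSpectrum(freqs, mags, N, x.rate)


def sliding_dft(x: Signal, N: int, M: int = 1) -> list[DftSpectrum]:
    """Full DFT recomputation at every window position (hop ``M``).

    Windows start at samples 0, M, 2M, ... while a complete window fits;
    no incremental-update shortcut is used — this is the unoptimized
    baseline by construction.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    xs = x.samples
    out = []
    for start in range(0, xs.size - N + 1, M):
        seg = Signal(xs[start : start + N], x.rate)
        out.append(dft_power_spectrum(seg, N))
    return out


def dft_resolution(rate: float, N: int) -> float:
    """Uniform DFT bin spacing ``rate / N`` in Hz."""
    return rate / N


def nse_mean_resolution(grid: PeriodGrid) -> float:
    """Mean local resolution ``(1/|grid|) * sum_w rate / w^2`` in Hz."""
    w = grid.periods.astype(np.float64)
    return float(np.mean(grid.rate / (w * w)))


def band_bin_count(rate: float, N: int, f_lo: float, f_hi: float) -> int:
    """Number of DFT bins ``k*rate/N`` inside ``[f_lo, f_hi]`` inclusive."""
    k_lo = math.ceil(f_lo * N / rate)
    k_hi = math.floor(f_hi * N / rate)
    return max(0, k_hi - k_lo + 1)
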