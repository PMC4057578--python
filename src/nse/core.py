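"""Offline ensemble-average power spectral estimation.

The estimator detects periodicity in a zero-mean, unit-variance signal by
averaging consecutive segments of length ``w``: if the signal repeats with
period ``w`` samples, the ``n = floor(N/w)`` segments reinforce each other
and the ensemble mean has a large norm; for uncorrelated noise the mean
shrinks like ``1/sqrt(n)``.  Scanning ``w`` over every integer period in a
frequency band (``f = rate / w``) yields a power spectrum on a period-domain
grid whose resolution at low frequencies is much finer than a DFT bin.

The spectral point for period ``w`` is computed as

    S_w = (1 / sqrt(N)) * || sum_i x_{w,i} ||_2

the Euclidean norm of the vector of per-position segment sums scaled by
``1/sqrt(N)``.  This equals ``sqrt(n) * P_wRMS`` (RMS ensemble power scaled
by ``sqrt(n)``) up to the ``n*w ~ N`` approximation; the ``sqrt(n)`` factor
flattens the white-noise baseline across periods so that peaks at different
frequencies are directly comparable.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import (
    BandTooNarrowError,
    DegenerateSignalError,
    WindowTooShortError,
)

__all__ = [
    "Signal",
    "PeriodGrid",
    "Spectrum",
    "EnsembleMean",
    "normalize_signal",
    "build_period_grid",
    "segment_count",
    "ensemble_mean",
    "nse_spectrum_offline",
    "nse_spectrum_offline_halved",
]

#: electrophysiologic dominant-frequency band (Hz)
DEFAULT_BAND = (3.0, 12.0)
#: nominal acquisition rate of bipolar atrial electrograms (Hz)
DEFAULT_RATE = 977.0
#: analysis window, ~8 s at 977 Hz
DEFAULT_WINDOW = 8192


@dataclasses.dataclass(frozen=True)
class Signal:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    samples
        Real-valued samples (arbitrary units, typically mV).
    rate
        Sampling rate in Hz; must be positive.
    normalized
        True once the signal has been standardized to zero mean and unit
        (population) variance.  Setting the flag on data that is not
        standardized raises ``ValueError``.
    """

    samples: np.ndarray
    rate: float
    normalized: bool = False

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        if self.normalized:
            mean = float(samples.mean())
            var = float(samples.var())
            if abs(mean) >= 1e-9 or abs(var - 1.0) >= 1e-6:
                raise ValueError(
                    "normalized flag set but mean/variance are "
                    f"{mean:.3g}/{var:.6g}"
                )

    def __len__(self) -> int:
        return self.samples.size


@dataclasses.dataclass(frozen=True)
class PeriodGrid:
    """Ordered candidate periods ``w`` and their frequencies for a band.

    Periods are strictly decreasing integers, so ``frequencies = rate /
    periods`` is strictly increasing.  Spectra evaluated on the grid are
    therefore stored in ascending-frequency order.
    """

    periods: np.ndarray
    frequencies: np.ndarray
    rate: float
    band: tuple[float, float]

    def __post_init__(self):
        periods = np.asarray(self.periods, dtype=np.int64)
        frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if periods.size == 0:
            raise BandTooNarrowError("period grid is empty")
        if periods.size > 1 and not np.all(np.diff(periods) < 0):
            raise ValueError("periods must be strictly decreasing")
        if np.any(periods < 1):
            raise ValueError("periods must be >= 1 sample")
        if not np.array_equal(frequencies, self.rate / periods):
            raise ValueError("frequencies must equal rate / periods exactly")
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "frequencies", frequencies)

    def __len__(self) -> int:
        return self.periods.size


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """Spectral magnitude values on a period-domain grid.

    ``values[i]`` is the (nonnegative) spectral point for
    ``grid.periods[i]``; ``time_index`` is the global sample counter at
    which a streaming spectrum is valid (None for offline block spectra).
    """

    grid: PeriodGrid
    values: np.ndarray
    time_index: int | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.grid),):
            raise ValueError(
                f"values length {values.size} != grid length {len(self.grid)}"
            )
        if np.any(values < 0):
            raise ValueError("spectral values must be nonnegative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclasses.dataclass(frozen=True)
class EnsembleMean:
    """Element-wise average of ``n`` consecutive length-``w`` segments."""

    w: int
    values: np.ndarray
    n: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.size != self.w:
            raise ValueError("ensemble-mean length must equal the period w")
        object.__setattr__(self, "values", values)


def normalize_signal(raw: Signal, channel=None) -> Signal:
    """Standardize a signal to zero mean and unit population variance.

    The population convention (divisor = length) is used throughout the
    package.  Idempotent up to floating-point roundoff.

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (zero variance) or has fewer than two
        samples; ``channel`` (an optional name/index) is included in the
        message to identify the offender in multichannel runs.
    """
    x = raw.samples
    if x.size < 2:
        raise DegenerateSignalError(
            "cannot normalize a signal with fewer than 2 samples", channel
        )
    mean = x.mean()
    sd = x.std()  # population convention
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSignalError(
            "zero-variance (constant) signal cannot be normalized", channel
        )
    return Signal((x - mean) / sd, raw.rate, normalized=True)


def build_period_grid(rate: float, f_lo: float, f_hi: float) -> PeriodGrid:
    """Build the period grid for a frequency band.

    Candidate periods are every integer ``w`` from ``floor(rate/f_lo)`` down
    to ``floor(rate/f_hi)``; the matching frequencies are ``rate / w``.
    Taking the floor at both edges reproduces the canonical 325..81 range
    (245 points) at 977 Hz for the 3-12 Hz electrophysiologic band, even
    though 977/81 = 12.06 Hz slightly exceeds the upper edge.
    """
    if not (0 < f_lo < f_hi < rate / 2):
        raise ValueError(
            f"need 0 < f_lo < f_hi < rate/2, got ({f_lo}, {f_hi}) at {rate} Hz"
        )
    w_max = math.floor(rate / f_lo)
    w_min = math.floor(rate / f_hi)
    if w_max < w_min:
        raise BandTooNarrowError(
            f"band ({f_lo}, {f_hi}) Hz at {rate} Hz contains no integer period"
        )
    periods = np.arange(w_max, w_min - 1, -1, dtype=np.int64)
    return PeriodGrid(periods, rate / periods, float(rate), (f_lo, f_hi))


def segment_count(N: int, w: int) -> int:
    """Number of whole length-``w`` segments in a length-``N`` window."""
    if w < 1:
        raise ValueError("period w must be >= 1")
    if w > N:
        raise WindowTooShortError(f"period w={w} exceeds window length N={N}")
    return N // w


def _segment_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Per-position sums over the first ``floor(N/w)`` segments of length w."""
    n = segment_count(x.size, w)
    return x[: n * w].reshape(n, w).sum(axis=0)


def ensemble_mean(x: Signal, w: int) -> EnsembleMean:
    """Average of consecutive length-``w`` segments of the signal.

    Samples beyond ``n*w`` (the trailing remainder) are discarded.
    ``values[j] = (1/n) * sum_i x[i*w + j]``.
    """
    n = segment_count(len(x), w)
    return EnsembleMean(w, _segment_sums(x.samples, w) / n, n)


def nse_spectrum_offline(x: Signal, grid: PeriodGrid) -> Spectrum:
    """Block (offline) ensemble-average power spectrum.

    For each period ``w`` in the grid,
    ``S_w = ||segment sums||_2 / sqrt(N)`` with ``N = len(x)``.  The input
    is expected to be normalized to zero mean and unit variance; on white
    noise the spectrum then has a flat baseline near 1, and an exactly
    ``w0``-periodic signal with ``N = n*w0`` peaks at ``S_w0 = sqrt(n)``.
    """
    xs = x.samples
    N = xs.size
    w_max = int(grid.periods.max())
    if N < w_max:
        raise WindowTooShortError(
            f"signal length {N} shorter than longest grid period {w_max}"
        )
    inv_sqrt_n = 1.0 / math.sqrt(N)
    values = np.empty(len(grid))
    for i, w in enumerate(grid.periods):
        s = _segment_sums(xs, int(w))
        values[i] = math.sqrt(float(np.dot(s, s))) * inv_sqrt_n
    return Spectrum(grid, values)


def nse_spectrum_offline_halved(x: Signal, grid: PeriodGrid) -> Spectrum:
    """Offline spectrum using the half-period redundancy shortcut.

    Where ``2w`` is also on the grid, the segment-sum vector for ``w`` is
    formed by adding the two halves of the vector for ``2w`` instead of
    re-summing the signal.  This is exact whenever ``floor(N/w)`` is even
    (``= 2*floor(N/2w)``); when it is odd the shortcut omits the final
    segment — a documented approximation, which is why the direct path
    (:func:`nse_spectrum_offline`) is the package reference.
    """
    xs = x.samples
    N = xs.size
    w_max = int(grid.periods.max())
    if N < w_max:
        raise WindowTooShortError(
            f"signal length {N} shorter than longest grid period {w_max}"
        )
    inv_sqrt_n = 1.0 / math.sqrt(N)
    available: dict[int, np.ndarray] = {}
    values = np.empty(len(grid))
    # periods are decreasing, so 2w is computed before w is needed
    for i, wi in enumerate(grid.periods):
        w = int(wi)
        if 2 * w in available:
            s2 = available[2 * w]
            s = s2[:w] + s2[w:]
        else:
            s = _segment_sums(xs, w)
        available[w] = s
        values[i] = math.sqrt(float(np.dot(s, s))) * inv_sqrt_n
    return Spectrum(grid, values)
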