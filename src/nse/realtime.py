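"""Per-sample streaming ensemble-average spectral estimation.

The block ensemble mean of :mod:`nse.core` is replaced by an exponential
moving average so that one new input sample updates the whole spectrum in
O(number of periods) operations.  For each candidate period ``w`` the state
holds a ring buffer ``e`` of ``w`` ensemble-mean estimates (one per phase
position within the cycle); each incoming sample advances the wrap index by
one and refreshes a single slot with the low-pass recursion

    e[ind] <- c1 * e[ind] + c2 * x,    c1 = (n-1)/n,  c2 = 1/n,

where ``n = floor(N/w)`` is the number of segments the block estimator
would average over a window of ``N`` samples.  The running power
``P_w = sum_j e[j]^2`` is maintained incrementally by removing the old
squared slot value and adding the new one, so a full spectral update costs
one multiply-accumulate per period.  Spectral points are

    S_w = n * sqrt(P_w) / sqrt(N),

identical in scaling to the offline estimator, so offline and streaming
spectra of a stationary signal agree once the moving averages have
converged (geometric ratio ``c1`` per cycle revisit).

The moving size is fixed at M = 1: every input sample yields a valid
spectrum.  Early estimates (first ``N`` samples) are based on few prior
points and are rough; callers may discard them.
"""
from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .core import PeriodGrid, Signal, Spectrum, segment_count
from .errors import StreamCorruptError, WindowTooShortError

__all__ = [
    "StreamConfig",
    "StreamState",
    "moving_average_constants",
    "init_stream",
    "update",
    "stream_spectrum",
    "run_stream",
]

logger = logging.getLogger(__name__)


def moving_average_constants(N: int, w: int) -> tuple[float, float]:
    """Low-pass filter constants ``(c1, c2)`` for period ``w``.

    ``n = floor(N/w)``; ``c1 = (n-1)/n`` weights the prior estimate and
    ``c2 = 1/n`` the incoming sample, so ``c1 + c2*n = 1`` exactly and the
    effective averaging depth matches the block estimator's segment count.
    """
    n = segment_count(N, w)
    return (n - 1) / n, 1.0 / n


@dataclasses.dataclass(frozen=True)
class StreamConfig:
    """Configuration of a streaming estimator.

    ``window`` is the nominal averaging window N in samples (8192 by
    default, ~8 s at 977 Hz); ``move_size`` is the number of samples between
    successive spectra and is fixed at 1 (a spectrum per input sample).
    """

    grid: PeriodGrid
    window: int = 8192
    move_size: int = 1

    def __post_init__(self):
        if self.move_size != 1:
            raise ValueError("move_size is fixed at 1 (spectrum per sample)")
        w_max = int(self.grid.periods.max())
        if self.window < w_max:
            raise WindowTooShortError(
                f"window {self.window} shorter than longest period {w_max}"
            )

    @property
    def scale(self) -> float:
        """The constant 1/sqrt(window) applied to every spectral point."""
        return 1.0 / math.sqrt(self.window)


class StreamState:
    """Mutable per-channel streaming state, vectorized across all periods.

    The per-period ring buffers are stored in one flat array ``e`` with
    ``offsets[i]`` marking where period ``periods[i]``'s buffer begins, so a
    single fancy-indexed numpy operation touches exactly one slot per
    period on every update.  ``ind[i]`` is the slot written by the most
    recent sample and equals ``(k-1) mod w`` after ``k`` samples.
    """

    __slots__ = (
        "config", "periods", "n", "c1", "c2",
        "offsets", "e", "power", "ind", "k", "_warned_negative",
    )

    def __init__(self, config: StreamConfig):
        grid = config.grid
        periods = grid.periods.astype(np.int64)
        n = config.window // periods
        self.config = config
        self.periods = periods
        self.n = n.astype(np.float64)
        self.c1 = (n - 1) / n
        self.c2 = 1.0 / n
        self.offsets = np.concatenate(([0], np.cumsum(periods)[:-1]))
        self.e = np.zeros(int(periods.sum()))
        self.power = np.zeros(periods.size)
        # first update advances ind to 0, so the first sample lands on slot 0
        self.ind = periods - 1
        self.k = 0
        self._warned_negative = False

    def ensemble_buffer(self, w: int) -> np.ndarray:
        """Copy of the ring buffer for period ``w`` (slot j = phase j)."""
        i = int(np.nonzero(self.periods == w)[0][0])
        off = int(self.offsets[i])
        return self.e[off : off + w].copy()

    def recompute_power(self) -> np.ndarray:
        """Freshly computed ``sum_j e[j]^2`` per period (drift check)."""
        return np.add.reduceat(self.e * self.e, self.offsets)

    def resynchronize(self) -> None:
        """Replace the incrementally maintained power by the exact sum."""
        self.power = self.recompute_power()


def init_stream(config: StreamConfig) -> StreamState:
    """Fresh zero state: all buffers and powers zero, ``k = 0``."""
    return StreamState(config)


def update(state: StreamState, sample: float) -> StreamState:
    """Advance the stream by one input sample (in place).

    For every period: the wrap index advances by one (mod w), the slot at
    the index is refreshed with the moving-average recursion, and the
    running power is adjusted by the difference of squares.
    """
    if not np.isfinite(sample):
        raise StreamCorruptError(
            f"non-finite sample {sample!r} in input stream", k=state.k
        )
    ind = state.ind
    ind += 1
    ind[ind == state.periods] = 0
    idx = state.offsets + ind
    e_old = state.e[idx]
    e_new = state.c1 * e_old + state.c2 * sample
    state.e[idx] = e_new
    state.power += e_new * e_new - e_old * e_old
    state.k += 1
    return state


def stream_spectrum(state: StreamState) -> Spectrum:
    """Current spectrum ``S_w = n * sqrt(P_w) / sqrt(window)``.

    Tiny negative powers from floating-point drift are clamped to zero
    (logged once per state at debug level).
    """
    power = state.power
    if np.any(power < 0):
        if not state._warned_negative:
            logger.debug(
                "negative running power (min %.3g) clamped to 0 at k=%d",
                float(power.min()), state.k,
            )
            state._warned_negative = True
        power = np.maximum(power, 0.0)
    values = state.n * np.sqrt(power) * state.config.scale
    return Spectrum(state.config.grid, values, time_index=state.k)


def run_stream(
    x: Signal, config: StreamConfig, emit_every: int = 1
) -> list[Spectrum]:
    """Stream a whole signal, emitting a spectrum every ``emit_every`` samples.

    Computation is always per-sample (move size 1); ``emit_every`` only
    thins the emitted snapshots.  A final spectrum is always emitted at the
    last sample, so the last element equals ``stream_spectrum`` of the
    final state.
    """
    if emit_every < 1:
        raise ValueError("emit_every must be >= 1")
    state = init_stream(config)
    xs = x.samples
    out: list[Spectrum] = []
    for i in range(xs.size):
        update(state, xs[i])
        if (i + 1) % emit_every == 0:
            out.append(stream_spectrum(state))
    if xs.size % emit_every:
        out.append(stream_spectrum(state))
    return out
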