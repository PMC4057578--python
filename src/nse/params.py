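"""Spectral-parameter extraction: DA, DF, MP, SP.

Four scalar summaries of a band-limited power spectrum, defined for the
3-12 Hz electrophysiologic band:

* DF (dominant frequency, Hz): frequency of the largest spectral peak —
  a proxy for the local activation rate.
* DA (dominant amplitude): magnitude of that peak.
* MP / SP: mean and population standard deviation of the spectral profile
  after min-max normalization to [0, 1].  A peaky, organized spectrum has
  low MP; MP and SP are invariant under positive affine rescaling of the
  spectrum, so they compare across estimators with different amplitude
  conventions.

The dominant peak is taken as the global maximum over the band.  Because
the grid is confined to 3-12 Hz, the second harmonic of any DF above 6 Hz
falls outside the band, so no explicit harmonic screening is applied; ties
break toward the lowest frequency.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .core import Spectrum
from .errors import DegenerateSpectrumError

__all__ = [
    "SpectralParams",
    "dominant_peak",
    "profile_stats",
    "extract_params",
    "normalized_rms_difference",
]


@dataclasses.dataclass(frozen=True)
class SpectralParams:
    """Bundle of the four spectral parameters."""

    da: float  #: dominant amplitude (spectrum units)
    df: float  #: dominant frequency (Hz)
    mp: float  #: mean of the min-max normalized profile, in [0, 1]
    sp: float  #: population sd of the normalized profile, in [0, 0.5]


def _values(s) -> np.ndarray:
    return s.values if isinstance(s, Spectrum) else np.asarray(s, float)


def _is_flat(v: np.ndarray) -> bool:
    """Flat up to float rounding (e.g. a stream still in warm-up, whose
    values agree across periods except in the last ulp)."""
    return float(v.max()) - float(v.min()) <= 1e-9 * max(1.0, float(v.max()))


def dominant_peak(s: Spectrum) -> tuple[float, float]:
    """(DF, DA): frequency and amplitude of the band's largest peak.

    Ties break toward the lowest frequency.  A flat spectrum (all values
    equal, e.g. a stream still in warm-up) raises
    :class:`DegenerateSpectrumError`.
    """
    v = s.values
    if _is_flat(v):
        raise DegenerateSpectrumError("flat spectrum has no dominant peak")
    # frequencies ascend along the grid, so argmax's first-hit rule is the
    # lowest-frequency tie-break
    i = int(np.argmax(v))
    return float(s.grid.frequencies[i]), float(v[i])


def profile_stats(s: Spectrum | np.ndarray) -> tuple[float, float]:
    """(MP, SP) of the min-max normalized spectral profile."""
    v = _values(s)
    if _is_flat(v):
        raise DegenerateSpectrumError("flat spectrum has no profile")
    lo, hi = float(v.min()), float(v.max())
    p = (v - lo) / (hi - lo)
    return float(p.mean()), float(p.std())


def extract_params(s: Spectrum) -> SpectralParams:
    """All four parameters of a spectrum."""
    df, da = dominant_peak(s)
    mp, sp = profile_stats(s)
    return SpectralParams(da=da, df=df, mp=mp, sp=sp)


def normalized_rms_difference(a: Spectrum | np.ndarray,
                              b: Spectrum | np.ndarray) -> float:
    """RMS difference between two spectra after standardizing each.

    Both spectra are scaled to zero mean and unit (population) variance
    before differencing, so only shapes are compared — the protocol used to
    overlap offline and real-time spectra.  Identical shapes give 0.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError("spectra must share a grid")
    za = (va - va.mean()) / va.std()
    zb = (vb - vb.mean()) / vb.std()
    return float(np.sqrt(np.mean((za - zb) ** 2)))
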