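"""Qualified-extremum selection used by the kinematic and inertial detectors.

A *qualifying* local maximum must (1) be a strict local maximum, (2) have
topographic prominence at least ``prominence_floor``, and (3) survive greedy
acceptance in order of decreasing amplitude subject to a minimum index
separation.  Minima are found by negating the signal.  The same rules are
brute-force re-derivable sample by sample, which the test suite exploits.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .errors import ParameterError

__all__ = ["qualified_maxima", "qualified_minima", "estimate_dominant_period",
           "estimate_step_period"]


def qualified_maxima(x: np.ndarray, prominence_floor: float = 0.0,
                     min_separation: int = 1) -> np.ndarray:
    """Indices of qualifying local maxima of ``x`` (see module docstring)."""
    x = np.asarray(x, dtype=float)
    if min_separation < 1:
        raise ParameterError("min_separation must be >= 1 sample")
    cand, _ = find_peaks(x)
    if cand.size == 0:
        return cand
    prom = peak_prominences(x, cand)[0]
    cand = cand[prom >= prominence_floor]
    if cand.size == 0:
        return cand
    # Greedy acceptance in descending amplitude with separation constraint.
    order = cand[np.argsort(-x[cand], kind="stable")]
    accepted: list[int] = []
    for idx in order:
        if all(abs(idx - a) >= min_separation for a in accepted):
            accepted.append(int(idx))
    return np.array(sorted(accepted), dtype=int)


def qualified_minima(x: np.ndarray, prominence_floor: float = 0.0,
                     min_separation: int = 1) -> np.ndarray:
    """Indices of qualifying local minima of ``x``."""
    return qualified_maxima(-np.asarray(x, dtype=float),
                            prominence_floor, min_separation)


def iqr_prominence_floor(x: np.ndarray, fraction: float = 0.10) -> float:
    """Adaptive prominence floor: ``fraction`` of the robust (2nd-98th
    percentile) amplitude range.

    Suppresses noise- and filter-ripple-born extrema without hand tuning.
    A wide inter-percentile range is used rather than the inter-quartile
    range because gait velocity signals are quiet for most of the cycle, so
    their quartiles collapse onto the noise floor."""
    p2, p98 = np.percentile(np.asarray(x, dtype=float), [2, 98])
    return fraction * (p98 - p2)


def estimate_dominant_period(x: np.ndarray, fs: float,
                             fmin: float = 0.3, fmax: float = 5.0) -> float:
    """Dominant oscillation period (s) of ``x`` from its power spectrum,
    restricted to the plausible locomotor band [``fmin``, ``fmax``] Hz.

    Used to derive default wavelet scales and event-separation floors from
    the gait tempo itself."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    if n < 16:
        raise ParameterError("signal too short for spectral period estimation")
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not np.any(band) or spec[band].max() == 0:
        raise ParameterError("no spectral content in the locomotor band")
    f_dom = freqs[band][np.argmax(spec[band])]
    return 1.0 / f_dom


def estimate_step_period(x: np.ndarray, fs: float, lag_min: float = 0.3,
                         lag_max: float = 1.5) -> float:
    """Step period (s) as the first autocorrelation peak in
    [``lag_min``, ``lag_max``] seconds.

    More robust than a spectral peak for impact-like gait signals, whose
    power can concentrate on a harmonic of the step rate rather than the
    fundamental."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    if n < int(2 * lag_max * fs):
        raise ParameterError("signal too short for autocorrelation period estimate")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    ac = np.fft.irfft(spec)[: int(lag_max * fs) + 2]
    lo = int(lag_min * fs)
    seg = ac[lo:]
    peaks, _ = find_peaks(seg)
    if peaks.size == 0 or ac[0] == 0:
        raise ParameterError("no periodicity found in the lag window")
    # first peak that is a substantial fraction of the zero-lag power
    strong = peaks[ac[lo + peaks] > 0.2 * ac[0]]
    idx = strong[0] if strong.size else peaks[np.argmax(ac[lo + peaks])]
    return (lo + int(idx)) / fs
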