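"""Sacrum-IMU gait event detectors.

Two accelerometry methods working from a single sacral sensor; neither can
attribute events to a side, so both return ``foot="unassigned"`` series that
the evaluation layer matches side-agnostically.

* **IMU1** — integration + wavelet differentiation: the vertical
  acceleration is integrated with the trapezoidal rule (no zero-velocity
  update or drift correction; integration only serves as a low-pass step),
  then differentiated with a single-scale Gaussian-derivative continuous
  wavelet transform.  Heel strikes are the qualifying local minima of this
  first differentiated signal (S1); a second identical differentiation gives
  S2, whose qualifying local maxima are the toe-offs.
* **IMU2** — hierarchical coarse-peak + windowed refinement: after mean
  subtraction, 5th-order median filtering and per-axis max-abs amplitude
  normalization, per-cycle anchors are the maximum positive vertical peaks
  (minimum separation 0.35 s); each toe-off is the first negative local
  minimum of the vertical axis within 0.15 s after its anchor, and each heel
  strike is the minimum of the absolute AP first derivative within 0.15 s
  before its anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (AlignmentError, NormalizationDegenerateError,
                     ParameterError)
from .events import EventSeries
from .peaks import (estimate_step_period, iqr_prominence_floor,
                    qualified_maxima, qualified_minima)
from .signal_prep import (UniformSignal, butter_lowpass,
                          cwt_gaussian_derivative, median_filter, resample_to,
                          trapezoid_integrate)

__all__ = [
    "SacralAcc",
    "Imu1Intermediates",
    "Imu2Params",
    "preprocess_sacral",
    "default_cwt_scale",
    "imu1_detect",
    "imu2_preprocess",
    "imu2_detect",
]

log = logging.getLogger(__name__)


@dataclass
class SacralAcc:
    """Three-axis sacral acceleration (m/s^2)."""

    vertical: UniformSignal
    anteroposterior: UniformSignal
    mediolateral: UniformSignal

    def __post_init__(self) -> None:
        v, a, m = self.vertical, self.anteroposterior, self.mediolateral
        if not (v.fs == a.fs == m.fs and v.t0 == a.t0 == m.t0
                and len(v) == len(a) == len(m)):
            raise AlignmentError("sacral acceleration axes must share fs, t0 and length")

    @property
    def fs(self) -> float:
        return self.vertical.fs

    @property
    def t0(self) -> float:
        return self.vertical.t0

    def map(self, fn) -> "SacralAcc":
        return SacralAcc(fn(self.vertical), fn(self.anteroposterior),
                         fn(self.mediolateral))


def preprocess_sacral(acc: SacralAcc, fs_target: float = 1000.0,
                      cutoff: float = 30.0, order: int = 4) -> SacralAcc:
    """Standard accelerometry preprocessing: anti-aliased polyphase
    downsampling to ``fs_target`` followed by a zero-phase low-pass
    Butterworth filter."""
    def prep(sig: UniformSignal) -> UniformSignal:
        sig = resample_to(sig, fs_target, method="polyphase")
        return butter_lowpass(sig, cutoff, order=order, zero_phase=True)
    return acc.map(prep)


# ---------------------------------------------------------------------------
# IMU1


@dataclass
class Imu1Intermediates:
    """Intermediate series of the integration + CWT chain."""

    integrated: UniformSignal
    s1: UniformSignal
    s2: UniformSignal
    scale: float


def default_cwt_scale(vertical: UniformSignal) -> float:
    """Wavelet scale tied to gait tempo: ``fs / (10 * f_dom)``.

    ``f_dom`` is the dominant oscillation frequency of the vertical
    acceleration — the step rate — estimated from the first autocorrelation
    peak (robust against the spectral power of impact transients
    concentrating on a harmonic of the step rate)."""
    step_period = estimate_step_period(vertical.samples, vertical.fs)
    return max(4.0, vertical.fs * step_period / 10.0)


def imu1_detect(acc: SacralAcc, scale: float | None = None,
                min_event_separation: float | None = None,
                prominence_fraction: float = 0.10,
                ) -> tuple[EventSeries, Imu1Intermediates]:
    """Integration + Gaussian-CWT detector (vertical axis only).

    The vertical axis is mean-removed (offset invariance), integrated, and
    twice CWT-differentiated; heel strikes are qualifying minima of S1 and
    toe-offs qualifying maxima of S2.  Events carry no left/right attribution.
    """
    fs = acc.fs
    vertical = acc.vertical.with_samples(acc.vertical.samples - acc.vertical.samples.mean())
    if scale is None:
        scale = default_cwt_scale(vertical)
    if scale < 1:
        raise ParameterError("CWT scale must be >= 1 sample")
    if len(vertical) < 10 * scale:
        raise ParameterError(
            f"signal of {len(vertical)} samples too short for scale {scale}")

    integrated = trapezoid_integrate(vertical)
    s1 = cwt_gaussian_derivative(integrated, scale)
    s2 = cwt_gaussian_derivative(s1, scale)
    inter = Imu1Intermediates(integrated, s1, s2, scale)

    if np.ptp(s1.samples) == 0:
        return EventSeries("imu1", "unassigned"), inter

    if min_event_separation is None:
        min_event_separation = 0.5 * estimate_step_period(
            acc.vertical.samples, fs)
    sep = max(1, int(round(min_event_separation * fs)))

    hs_idx = qualified_minima(s1.samples,
                              iqr_prominence_floor(s1.samples, prominence_fraction),
                              sep)
    to_idx = qualified_maxima(s2.samples,
                              iqr_prominence_floor(s2.samples, prominence_fraction),
                              sep)
    return (EventSeries("imu1", "unassigned",
                        (acc.t0 + hs_idx / fs).tolist(),
                        (acc.t0 + to_idx / fs).tolist()),
            inter)


# ---------------------------------------------------------------------------
# IMU2


@dataclass(frozen=True)
class Imu2Params:
    """Hierarchical coarse-peak detector parameters."""

    min_peak_separation: float = 0.35  # s, between coarse vertical peaks
    refine_window: float = 0.15        # s, TO after / HS before each anchor
    median_order: int = 5              # artifact-removal median filter
    min_peak_height: float = 0.3       # normalized units, anchor candidacy

    def __post_init__(self) -> None:
        if min(self.min_peak_separation, self.refine_window) <= 0:
            raise ParameterError("window durations must be positive")
        if self.median_order % 2 == 0 or self.median_order < 3:
            raise ParameterError("median_order must be odd and >= 3")


def imu2_preprocess(acc: SacralAcc, params: Imu2Params | None = None) -> SacralAcc:
    """Per-axis: subtract the mean (gravity removal), median-filter
    impulse-like artifacts, and normalize to unit maximum absolute value.
    Idempotent (to filter distortion) on already-normalized input."""
    params = params or Imu2Params()

    def prep(sig: UniformSignal) -> UniformSignal:
        x = sig.samples - sig.samples.mean()
        if np.all(x == 0.0):
            raise NormalizationDegenerateError(
                f"axis {sig.label!r} is constant; cannot amplitude-normalize")
        x = median_filter(sig.with_samples(x), params.median_order).samples
        peak = np.abs(x).max()
        if peak == 0.0:
            raise NormalizationDegenerateError(
                f"axis {sig.label!r} vanished after filtering; cannot normalize")
        return sig.with_samples(x / peak)

    return acc.map(prep)


def imu2_detect(acc: SacralAcc, params: Imu2Params | None = None) -> EventSeries:
    """Coarse-peak + windowed-refinement detector on preprocessed axes.

    Anchors are positive vertical local maxima of height at least
    ``min_peak_height``, accepted greedily in descending amplitude subject to
    ``min_peak_separation``.  Per anchor the toe-off is the first local
    minimum with negative value in ``(anchor, anchor + refine_window]`` and
    the heel strike the argmin of |d(AP)/dt| in
    ``[anchor - refine_window, anchor)``; anchors lacking either are dropped
    with a logged warning.
    """
    params = params or Imu2Params()
    fs = acc.fs
    v = acc.vertical.samples
    ap = acc.anteroposterior.samples
    sep = max(1, int(round(params.min_peak_separation * fs)))
    win = max(1, int(round(params.refine_window * fs)))

    anchors = qualified_maxima(v, prominence_floor=0.0, min_separation=sep)
    anchors = anchors[v[anchors] >= params.min_peak_height]
    if anchors.size == 0:
        return EventSeries("imu2", "unassigned")

    ap_slope = np.abs(np.gradient(ap) * fs)

    hs_times: list[float] = []
    to_times: list[float] = []
    for a in anchors:
        # toe-off: first negative-valued local minimum after the anchor
        seg = v[a + 1: min(a + 1 + win, v.size)]
        to_idx = None
        if seg.size >= 3:
            interior = np.nonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:])
                                  & (seg[1:-1] < 0.0))[0]
            if interior.size:
                to_idx = a + 2 + int(interior[0])
        # heel strike: flattest AP slope in the window before the anchor
        lo = max(0, a - win)
        hs_idx = None
        if a - lo >= 2:
            hs_idx = lo + int(np.argmin(ap_slope[lo:a]))
        if to_idx is None or hs_idx is None:
            log.warning("imu2: anchor at %.3f s lacks a qualifying refinement; dropped",
                        acc.t0 + a / fs)
            continue
        hs_times.append(acc.t0 + hs_idx / fs)
        to_times.append(acc.t0 + to_idx / fs)

    return EventSeries("imu2", "unassigned", sorted(set(hs_times)),
                       sorted(set(to_times)))
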