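"""Optical-motion-capture gait event detectors.

Two marker-based methods operating on calcaneus and first-metatarsal tracks:

* **OMC1** — the foot-velocity approach: heel strikes are the qualifying
  local minima (maximum downward velocity) of the calcaneus marker's
  vertical velocity; toe-offs are the qualifying local maxima (maximum
  upward velocity) of the metatarsal marker's vertical velocity.
* **OMC2** — the adaptive sagittal-velocity-threshold approach: for each
  gait cycle a per-step threshold is computed as mean + k*SD of the marker's
  sagittal speed inside a short stationary-contact window; the heel strike
  is the first sample after the swing where heel speed falls below its
  threshold, the toe-off the first sample after the metatarsal's quiet
  window where metatarsal speed exceeds its threshold.  The toe-off quiet
  window is 75 ms (lengthened from the original 50 ms to absorb
  low-amplitude pre-lift movement); the heel-strike window stays at 50 ms.

Both detectors expect tracks already preprocessed to 1000 Hz and low-pass
filtered (:func:`preprocess_track`; 15 Hz for OMC1, 10 Hz for OMC2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import AlignmentError, DegenerateThresholdError, ParameterError
from .events import EventSeries
from .peaks import (estimate_dominant_period, iqr_prominence_floor,
                    qualified_maxima, qualified_minima)
from .signal_prep import UniformSignal, butter_lowpass, derivative, resample_to

__all__ = [
    "MarkerTrack",
    "Omc2Params",
    "preprocess_track",
    "omc1_detect",
    "omc2_sagittal_speed",
    "omc2_cycle_anchors",
    "omc2_detect",
]

log = logging.getLogger(__name__)


@dataclass
class MarkerTrack:
    """Vertical + antero-posterior components of one foot marker (metres)."""

    vertical: UniformSignal
    anteroposterior: UniformSignal
    marker: str = "calcaneus"          # "calcaneus" | "metatarsal_1"
    foot: str = "left"

    def __post_init__(self) -> None:
        v, ap = self.vertical, self.anteroposterior
        if v.fs != ap.fs or v.t0 != ap.t0 or len(v) != len(ap):
            raise AlignmentError(
                f"marker {self.marker}/{self.foot}: components must share "
                f"fs, t0 and length")

    @property
    def fs(self) -> float:
        return self.vertical.fs

    @property
    def t0(self) -> float:
        return self.vertical.t0


def preprocess_track(track: MarkerTrack, fs_target: float = 1000.0,
                     cutoff: float = 15.0, order: int = 4) -> MarkerTrack:
    """Interpolate a raw marker track to ``fs_target`` (linear) and zero-phase
    low-pass filter both components (4th-order Butterworth by default)."""
    def prep(sig: UniformSignal) -> UniformSignal:
        sig = resample_to(sig, fs_target, method="linear_interpolation")
        return butter_lowpass(sig, cutoff, order=order, zero_phase=True)
    return MarkerTrack(prep(track.vertical), prep(track.anteroposterior),
                       track.marker, track.foot)


def _check_aligned(a: MarkerTrack, b: MarkerTrack) -> None:
    if a.fs != b.fs or a.t0 != b.t0 or len(a.vertical) != len(b.vertical):
        raise AlignmentError("calcaneus and metatarsal tracks are not aligned")


# ---------------------------------------------------------------------------
# OMC1 — foot-velocity extrema


def omc1_detect(calcaneus: MarkerTrack, metatarsal: MarkerTrack,
                min_event_separation: float | None = None,
                prominence_fraction: float = 0.10) -> EventSeries:
    """Foot-velocity detector.

    Qualifying extrema require topographic prominence of at least
    ``prominence_fraction`` of the velocity signal's inter-quartile range and
    pairwise separation of at least ``min_event_separation`` seconds
    (default: 0.4 x the dominant cycle period of the calcaneus velocity).
    Constant tracks produce an empty series.
    """
    _check_aligned(calcaneus, metatarsal)
    fs = calcaneus.fs
    v_cal = derivative(calcaneus.vertical)
    v_met = derivative(metatarsal.vertical)
    if np.ptp(v_cal.samples) == 0 and np.ptp(v_met.samples) == 0:
        return EventSeries("omc1", calcaneus.foot)

    if min_event_separation is None:
        min_event_separation = 0.4 * estimate_dominant_period(v_cal.samples, fs)
    if min_event_separation <= 0:
        raise ParameterError("min_event_separation must be positive")
    sep = max(1, int(round(min_event_separation * fs)))

    hs_idx = qualified_minima(v_cal.samples,
                              iqr_prominence_floor(v_cal.samples, prominence_fraction),
                              sep)
    to_idx = qualified_maxima(v_met.samples,
                              iqr_prominence_floor(v_met.samples, prominence_fraction),
                              sep)
    return EventSeries("omc1", calcaneus.foot,
                       (calcaneus.t0 + hs_idx / fs).tolist(),
                       (metatarsal.t0 + to_idx / fs).tolist())


# ---------------------------------------------------------------------------
# OMC2 — adaptive sagittal-velocity threshold


@dataclass(frozen=True)
class Omc2Params:
    """Parameters of the adaptive-threshold detector.

    ``threshold_floor`` (m/s) bounds the per-step threshold from below; it is
    required on noise-free signals, where a perfectly flat stationary window
    would otherwise yield a threshold of exactly zero.  ``crossing_hold``
    debounces the threshold crossing: the *mean* speed over the following
    ``crossing_hold`` seconds must be on the triggering side of the
    threshold, and the event is placed at the window start (isolated noise
    blips cannot trigger, while a genuine plateau — whose samples straddle a
    mean+SD threshold constantly — triggers at its onset).
    """

    quiet_window_hs: float = 0.050   # s
    quiet_window_to: float = 0.075   # s
    filter_cutoff: float = 10.0      # Hz
    filter_order: int = 4
    sd_multiplier: float = 1.0       # threshold = mean + k * SD
    threshold_floor: float | None = None  # m/s
    crossing_hold: float = 0.025     # s

    def __post_init__(self) -> None:
        if self.quiet_window_hs <= 0 or self.quiet_window_to <= 0:
            raise ParameterError("quiet windows must be positive")
        if self.filter_cutoff <= 0:
            raise ParameterError("filter cutoff must be positive")


def omc2_sagittal_speed(track: MarkerTrack) -> UniformSignal:
    """Resultant sagittal speed ``sqrt(v_vertical^2 + v_ap^2)`` in m/s."""
    if len(track.vertical) != len(track.anteroposterior):
        raise AlignmentError("marker components differ in length")
    vv = derivative(track.vertical).samples
    va = derivative(track.anteroposterior).samples
    return track.vertical.with_samples(np.hypot(vv, va),
                                       label=f"{track.marker}_speed")


def omc2_cycle_anchors(heel_speed: UniformSignal,
                       smooth_window: float = 0.25) -> np.ndarray:
    """Coarse gait-cycle anchors: per-cycle minima of the (smoothed) heel
    sagittal speed, one per stance, bracketing each swing.

    The speed is box-smoothed over ``smooth_window`` seconds, swing peaks are
    located with a separation floor of half the dominant cycle period, and
    one anchor is placed at the smoothed-speed minimum between consecutive
    swing peaks.  Head/tail anchors are added when a genuinely quiet region
    (below 20% of the peak speed) precedes the first or follows the last
    swing.  Returns anchor times in seconds.
    """
    fs = heel_speed.fs
    x = heel_speed.samples
    smooth = uniform_filter1d(x, size=max(3, int(round(smooth_window * fs))),
                              mode="nearest")
    period = estimate_dominant_period(smooth, fs)
    sep = max(1, int(round(0.5 * period * fs)))
    peaks = qualified_maxima(smooth, prominence_floor=0.25 * np.ptp(smooth),
                             min_separation=sep)
    if peaks.size < 2:
        return np.array([])
    anchors = []
    quiet_level = 0.2 * smooth.max()
    head = smooth[: peaks[0]]
    if head.size > int(0.05 * fs) and head.min() < quiet_level:
        anchors.append(int(np.argmin(head)))
    for a, b in zip(peaks[:-1], peaks[1:]):
        anchors.append(int(a + np.argmin(smooth[a:b])))
    tail = smooth[peaks[-1]:]
    if tail.size > int(0.05 * fs) and tail.min() < quiet_level:
        anchors.append(int(peaks[-1] + np.argmin(tail)))
    return heel_speed.t0 + np.array(sorted(anchors)) / fs


def _first_sustained(x: np.ndarray, threshold: float, hold: int,
                     below: bool) -> int | None:
    """First index whose forward ``hold``-sample window mean is below
    (``below=True``) or above the threshold.  Trailing windows are truncated
    at the array end."""
    if x.size == 0:
        return None
    hold = min(max(hold, 1), x.size)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = np.minimum(np.arange(x.size) + hold, x.size) - np.arange(x.size)
    win_mean = (csum[np.minimum(np.arange(x.size) + hold, x.size)]
                - csum[:-1]) / n
    mask = win_mean < threshold if below else win_mean > threshold
    idx = np.flatnonzero(mask)
    return int(idx[0]) if idx.size else None


def _window_threshold(speed: np.ndarray, center: int, half: int,
                      params: Omc2Params) -> float:
    lo, hi = max(0, center - half), min(speed.size, center + half + 1)
    win = speed[lo:hi]
    thr = float(win.mean() + params.sd_multiplier * win.std(ddof=1 if win.size > 1 else 0))
    if thr == 0.0:
        if params.threshold_floor is None:
            raise DegenerateThresholdError(
                "stationary window has zero mean and zero variance; set "
                "Omc2Params.threshold_floor to a minimum speed threshold")
        thr = params.threshold_floor
    elif params.threshold_floor is not None:
        thr = max(thr, params.threshold_floor)
    return thr


def omc2_detect(calcaneus: MarkerTrack, metatarsal: MarkerTrack,
                params: Omc2Params | None = None,
                cycle_anchors: np.ndarray | None = None) -> EventSeries:
    """Adaptive sagittal-velocity-threshold detector.

    ``cycle_anchors`` partition the trial into gait cycles (mid-stance heel
    speed minima); when omitted they are computed with
    :func:`omc2_cycle_anchors`.  Cycles in which no threshold crossing is
    found are skipped with a logged warning.
    """
    params = params or Omc2Params()
    _check_aligned(calcaneus, metatarsal)
    fs = calcaneus.fs
    heel_speed = omc2_sagittal_speed(calcaneus).samples
    met_speed = omc2_sagittal_speed(metatarsal).samples
    if cycle_anchors is None:
        cycle_anchors = omc2_cycle_anchors(omc2_sagittal_speed(calcaneus))
    anchors = np.round((np.asarray(cycle_anchors, dtype=float) - calcaneus.t0) * fs).astype(int)
    anchors = anchors[(anchors >= 0) & (anchors < heel_speed.size)]
    # virtual end boundary so the tail cycle after the last anchor is scanned
    if anchors.size and anchors[-1] < heel_speed.size - 1:
        anchors = np.append(anchors, heel_speed.size - 1)

    half_hs = max(1, int(round(params.quiet_window_hs * fs / 2)))
    half_to = max(1, int(round(params.quiet_window_to * fs / 2)))
    smooth = uniform_filter1d(heel_speed, size=max(3, int(round(0.1 * fs))),
                              mode="nearest")
    met_smooth = uniform_filter1d(met_speed, size=max(3, int(round(0.1 * fs))),
                                  mode="nearest")

    hs_times: list[float] = []
    to_times: list[float] = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        # --- heel strike: quiet window in the stance *after* this cycle's swing
        swing = a + int(np.argmax(smooth[a:b]))
        post = smooth[swing:b]
        if post.size < 2:
            log.warning("omc2: cycle at %.3f s has no post-swing stance; skipped",
                        calcaneus.t0 + a / fs)
            continue
        q_hs = swing + int(np.argmin(post))
        thr_hs = _window_threshold(heel_speed, q_hs, half_hs, params)
        hold = max(1, int(round(params.crossing_hold * fs)))
        below = _first_sustained(heel_speed[swing:q_hs + 1], thr_hs, hold,
                                 below=True)
        if below is not None:
            hs_times.append(calcaneus.t0 + (swing + below) / fs)
        else:
            log.warning("omc2: no sub-threshold heel sample in cycle at %.3f s; skipped",
                        calcaneus.t0 + a / fs)

        # --- toe-off: metatarsal quiet window *before* its lift in this cycle
        m_peak = a + int(np.argmax(met_smooth[a:b]))
        pre = met_smooth[a:m_peak]
        if pre.size < 2:
            log.warning("omc2: cycle at %.3f s has no pre-lift metatarsal stance; skipped",
                        calcaneus.t0 + a / fs)
            continue
        q_to = a + int(np.argmin(pre))
        thr_to = _window_threshold(met_speed, q_to, half_to, params)
        start = min(q_to + half_to, m_peak)
        above = _first_sustained(met_speed[start:b], thr_to,
                                 max(1, int(round(params.crossing_hold * fs))),
                                 below=False)
        if above is not None:
            to_times.append(calcaneus.t0 + (start + above) / fs)
        else:
            log.warning("omc2: no supra-threshold metatarsal sample in cycle at %.3f s; skipped",
                        calcaneus.t0 + a / fs)

    return EventSeries("omc2", calcaneus.foot, sorted(set(hs_times)),
                       sorted(set(to_times)))
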