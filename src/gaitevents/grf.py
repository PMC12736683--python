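"""Gold-standard gait event detection from vertical ground reaction force.

Heel strike is the first sample at or above a fixed force threshold (15 N by
default) and toe-off the first sample below it after a stance, on the *raw*
(unfiltered) force.  Because raw force thresholding chatters on noisy data,
two debounce durations are applied: sub-threshold gaps shorter than
``min_flight`` are merged into the surrounding stance, and supra-threshold
runs shorter than ``min_stance`` are discarded.  Both defaults are far below
physiological stance/swing times.  Runs touching the first or last sample
are dropped (their onset or offset is outside the record).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .events import EventSeries
from .signal_prep import UniformSignal

__all__ = ["detect_grf_events"]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where ``mask`` is True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_grf_events(vgrf: UniformSignal, threshold: float = 15.0,
                      min_stance: float = 0.100, min_flight: float = 0.050,
                      foot: str = "left") -> EventSeries:
    """Threshold-crossing event detection on a vertical GRF channel.

    Returns an empty series (not an error) when the force never reaches the
    threshold.
    """
    if threshold <= 0:
        raise ParameterError("force threshold must be positive")
    if min_stance < 0 or min_flight < 0:
        raise ParameterError("debounce durations must be non-negative")

    fs = vgrf.fs
    above = vgrf.samples >= threshold
    runs = _runs(above)
    if not runs:
        return EventSeries("grf", foot)

    # merge sub-threshold gaps shorter than min_flight
    gap_samples = int(round(min_flight * fs))
    merged: list[list[int]] = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] < gap_samples:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    # discard short runs and runs touching the record edges
    stance_samples = int(round(min_stance * fs))
    n = vgrf.samples.size
    hs, to = [], []
    for start, end in merged:
        if end - start < stance_samples:
            continue
        if start == 0 or end == n:
            continue
        hs.append(vgrf.t0 + start / fs)
        to.append(vgrf.t0 + end / fs)

    return EventSeries("grf", foot, hs, to)
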