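"""Validation layer: event matching, timing-error statistics and agreement.

Detected events are paired one-to-one with reference events (greedy
nearest-neighbour in ascending absolute error, within a tolerance that
defaults to half the reference's median stride period).  From the matched
pairs the layer computes per-participant root-mean-square error, range of
prediction errors, stance times, intra-subject variability
(ISV = SD / mean x 100, the coefficient of variation), Bland-Altman
agreement (mean difference and 95% limits of agreement) and the Pearson
correlation of per-participant mean stance times, with the correlation
classified as low (r <= 0.3), moderate (0.4 < r <= 0.6) or high (r > 0.6);
values in the undefined band (0.3, 0.4] are labelled "unclassified-gap".
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import PairingError, UndefinedStatisticError
from .events import EventSeries

__all__ = [
    "MatchedErrors",
    "StanceRecord",
    "ValidationReport",
    "match_events",
    "match_times",
    "rmse",
    "error_range",
    "stance_times",
    "isv",
    "bland_altman",
    "pearson_agreement",
    "classify_r",
    "default_tolerance",
    "build_report",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Matching


@dataclass
class MatchedErrors:
    """Paired (detected, reference) events of one type with signed errors
    (detected - reference, seconds)."""

    method: str
    event_type: str  # "heel_strike" | "toe_off"
    pairs: list[tuple[float, float, float]] = field(default_factory=list)
    unmatched_detected: int = 0
    unmatched_reference: int = 0

    @property
    def errors(self) -> np.ndarray:
        return np.array([e for _, _, e in self.pairs])

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_times(detected, reference, tolerance: float,
                method: str = "", event_type: str = "") -> MatchedErrors:
    """Greedy one-to-one nearest pairing of two timestamp lists.

    Candidate pairs within ``tolerance`` are accepted in ascending absolute
    error; each detected and each reference time is used at most once.
    An empty reference leaves every detected event unmatched (not an error).
    """
    if tolerance <= 0:
        raise PairingError("matching tolerance must be positive")
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    cands = [(abs(d - r), i, j)
             for i, d in enumerate(det) for j, r in enumerate(ref)
             if abs(d - r) <= tolerance]
    cands.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((float(det[i]), float(ref[j]), float(det[i] - ref[j])))
    pairs.sort(key=lambda p: p[1])
    return MatchedErrors(method, event_type, pairs,
                         unmatched_detected=det.size - len(used_d),
                         unmatched_reference=ref.size - len(used_r))


def match_events(detected: EventSeries, reference: EventSeries,
                 tolerance: float) -> tuple[MatchedErrors, MatchedErrors]:
    """Match one detected series against a reference series; returns the
    (heel_strike, toe_off) :class:`MatchedErrors` pair."""
    hs = match_times(detected.heel_strikes, reference.heel_strikes, tolerance,
                     detected.method, "heel_strike")
    to = match_times(detected.toe_offs, reference.toe_offs, tolerance,
                     detected.method, "toe_off")
    return hs, to


def default_tolerance(reference: EventSeries) -> float:
    """Half the reference's median stride period.

    For side-agnostic (merged) references consecutive heel strikes are one
    *step* apart, so the stride is twice the median spacing."""
    hs = np.asarray(reference.heel_strikes, dtype=float)
    if hs.size < 3:
        return 0.5  # fallback for degenerate references
    spacing = float(np.median(np.diff(hs)))
    stride = 2.0 * spacing if reference.foot == "unassigned" else spacing
    return 0.5 * stride


# ---------------------------------------------------------------------------
# Scalar statistics


def rmse(errors) -> float:
    """Root-mean-square of signed errors."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise UndefinedStatisticError("RMSE of an empty error list is undefined")
    return float(np.sqrt(np.mean(e ** 2)))


def error_range(errors) -> float:
    """max - min of the signed errors (0 for a single element)."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise UndefinedStatisticError("range of an empty error list is undefined")
    return float(e.max() - e.min())


def isv(values) -> float:
    """Intra-subject variability: sample SD / mean x 100 (percent)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UndefinedStatisticError("ISV needs at least two values")
    mean = float(v.mean())
    if mean <= 0:
        raise UndefinedStatisticError("ISV undefined for non-positive mean")
    return float(np.std(v, ddof=1) / mean * 100.0)


def bland_altman(reference_values, method_values) -> dict[str, float]:
    """Mean difference (method - reference) and 95% limits of agreement
    (mean +/- 1.96 x sample SD of the differences)."""
    ref = np.asarray(reference_values, dtype=float)
    met = np.asarray(method_values, dtype=float)
    if ref.size != met.size:
        raise PairingError("Bland-Altman requires paired sequences of equal length")
    if ref.size < 3:
        raise UndefinedStatisticError("Bland-Altman needs at least 3 pairs")
    d = met - ref
    mean_diff = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return {"mean_diff": mean_diff,
            "loa_low": mean_diff - 1.96 * sd,
            "loa_high": mean_diff + 1.96 * sd}


def classify_r(r: float) -> str:
    if r <= 0.3:
        return "low"
    if r <= 0.4:
        return "unclassified-gap"
    if r <= 0.6:
        return "moderate"
    return "high"


def pearson_agreement(x, y) -> tuple[float, str]:
    """Pearson r plus its qualitative class (see module docstring)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise PairingError("correlation requires equal-length sequences")
    if x.size < 3:
        raise UndefinedStatisticError("correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    r = float(pearsonr(x, y).statistic)
    return r, classify_r(r)


# ---------------------------------------------------------------------------
# Stance times


@dataclass
class StanceRecord:
    """Per-series stance durations (heel strike to following toe-off)."""

    method: str
    foot: str
    stance_times: list[float] = field(default_factory=list)
    #: heel-strike time that starts each stance (parallel to stance_times)
    onsets: list[float] = field(default_factory=list)
    n_dropped: int = 0


def stance_times(events: EventSeries, max_stance: float = 2.0,
                 literal_swing: bool = False) -> StanceRecord:
    """Stance duration per gait cycle.

    Standard reading: each heel strike pairs with the next toe-off before the
    following heel strike.  ``literal_swing=True`` instead pairs each toe-off
    with the next heel strike (the swing interval).  Non-positive or
    implausibly long (> ``max_stance``) durations are dropped and counted.

    For a side-agnostic (``foot="unassigned"``) series, consecutive events
    alternate feet, so a heel strike's own toe-off is *not* the next one
    (that belongs to the contralateral foot lifting during double support)
    but the first toe-off after the *next* heel strike; the pairing skips
    one event accordingly.
    """
    starts = events.toe_offs if literal_swing else events.heel_strikes
    ends = events.heel_strikes if literal_swing else events.toe_offs
    ends_arr = np.asarray(ends, dtype=float)
    starts_arr = np.asarray(starts, dtype=float)
    skip = 1 if events.foot == "unassigned" else 0
    rec = StanceRecord(events.method, events.foot)
    for i, s in enumerate(starts_arr):
        if i + skip >= starts_arr.size:
            break
        lo = starts_arr[i + skip] if skip else s
        hi = (starts_arr[i + skip + 1] if i + skip + 1 < starts_arr.size
              else math.inf)
        after = ends_arr[(ends_arr > lo) & (ends_arr < hi)]
        if after.size == 0:
            continue
        dur = float(after[0] - s)
        if 0.0 < dur <= max_stance:
            rec.stance_times.append(dur)
            rec.onsets.append(float(s))
        else:
            rec.n_dropped += 1
    return rec


# ---------------------------------------------------------------------------
# Report


@dataclass
class MethodSummary:
    method: str
    hs_rmse: float | None = None          # s, mean of per-participant RMSE
    hs_rmse_sd: float | None = None
    to_rmse: float | None = None
    to_rmse_sd: float | None = None
    hs_error_range: float | None = None   # s, mean of per-participant ranges
    to_error_range: float | None = None
    stance_mean: float | None = None      # s
    stance_isv: float | None = None       # %, mean of per-participant ISV
    bland_altman: dict[str, float] | None = None
    pearson_r: float | None = None
    pearson_class: str | None = None
    n_matched_hs: int = 0
    n_matched_to: int = 0
    n_unmatched_detected: int = 0
    n_unmatched_reference: int = 0


@dataclass
class ValidationReport:
    reference: str
    n_participants: int
    methods: dict[str, MethodSummary] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)
    matched_pairs: pd.DataFrame | None = None
    stance_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"reference": self.reference,
               "n_participants": self.n_participants,
               "failures": list(self.failures),
               "methods": {k: asdict(v) for k, v in self.methods.items()}}
        return out


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def build_report(detections: list[dict[str, list[EventSeries]]],
                 references: list[dict[str, EventSeries]],
                 reference_name: str = "grf",
                 tolerance: float | None = None,
                 max_stance: float = 2.0) -> ValidationReport:
    """Aggregate a multi-participant validation study.

    ``detections[p][method]`` holds the event series (one per foot, or one
    unassigned) of participant ``p``; ``references[p]`` maps "left"/"right"
    to that participant's reference series.  Statistics are computed per
    participant and then averaged across participants; Bland-Altman pools
    matched stance pairs across everyone.
    """
    if len(detections) != len(references):
        raise PairingError("detections and references differ in participants")
    n_p = len(detections)
    report = ValidationReport(reference_name, n_p)
    methods = sorted({m for det in detections for m in det})
    pair_rows = []
    stance_rows = []

    for m in methods:
        per_hs_rmse, per_to_rmse = [], []
        per_hs_range, per_to_range = [], []
        per_stance_mean, per_stance_isv = [], []
        per_ref_stance_mean = []
        ba_ref, ba_met = [], []
        n_hs = n_to = n_ud = n_ur = 0

        for p, (det, refs) in enumerate(zip(detections, references)):
            series_list = det.get(m)
            if not series_list:
                continue
            hs_err, to_err, stances = [], [], []
            ref_stance_all = []
            for foot in ("left", "right"):
                rrec = stance_times(refs[foot], max_stance)
                ref_stance_all.extend(rrec.stance_times)
            merged_ref = None
            for ds in series_list:
                if ds.foot == "unassigned":
                    if merged_ref is None:
                        hs = sorted(refs["left"].heel_strikes + refs["right"].heel_strikes)
                        to = sorted(refs["left"].toe_offs + refs["right"].toe_offs)
                        merged_ref = EventSeries(reference_name, "unassigned", hs, to)
                    ref = merged_ref
                else:
                    ref = refs[ds.foot]
                tol = tolerance if tolerance is not None else default_tolerance(ref)
                me_hs, me_to = match_events(ds, ref, tol)
                hs_err.extend(me_hs.errors.tolist())
                to_err.extend(me_to.errors.tolist())
                n_hs += me_hs.n_matched
                n_to += me_to.n_matched
                n_ud += me_hs.unmatched_detected + me_to.unmatched_detected
                n_ur += me_hs.unmatched_reference + me_to.unmatched_reference
                for me in (me_hs, me_to):
                    for d_t, r_t, e in me.pairs:
                        pair_rows.append((p, m, ds.foot, me.event_type, d_t, r_t, e))
                # stance pairing for Bland-Altman via matched heel strikes
                drec = stance_times(ds, max_stance)
                rrec = stance_times(ref, max_stance)
                d_map = dict(zip(drec.onsets, drec.stance_times))
                r_map = dict(zip(rrec.onsets, rrec.stance_times))
                for d_t, r_t, _ in me_hs.pairs:
                    if d_t in d_map and r_t in r_map:
                        ba_met.append(d_map[d_t])
                        ba_ref.append(r_map[r_t])
                stances.extend(drec.stance_times)
                for s_on, s_dur in zip(drec.onsets, drec.stance_times):
                    stance_rows.append((p, m, ds.foot, s_on, s_dur))

            if hs_err:
                per_hs_rmse.append(rmse(hs_err))
                per_hs_range.append(error_range(hs_err))
            if to_err:
                per_to_rmse.append(rmse(to_err))
                per_to_range.append(error_range(to_err))
            if stances:
                per_stance_mean.append(float(np.mean(stances)))
                if len(stances) >= 2 and np.mean(stances) > 0:
                    per_stance_isv.append(isv(stances))
            if ref_stance_all:
                per_ref_stance_mean.append(float(np.mean(ref_stance_all)))

        summary = MethodSummary(method=m, n_matched_hs=n_hs, n_matched_to=n_to,
                                n_unmatched_detected=n_ud,
                                n_unmatched_reference=n_ur)
        summary.hs_rmse, summary.hs_rmse_sd = _mean_sd(per_hs_rmse)
        summary.to_rmse, summary.to_rmse_sd = _mean_sd(per_to_rmse)
        summary.hs_error_range, _ = _mean_sd(per_hs_range)
        summary.to_error_range, _ = _mean_sd(per_to_range)
        summary.stance_mean, _ = _mean_sd(per_stance_mean)
        summary.stance_isv, _ = _mean_sd(per_stance_isv)
        if len(ba_ref) >= 3:
            summary.bland_altman = bland_altman(ba_ref, ba_met)
        if (len(per_stance_mean) >= 3
                and len(per_stance_mean) == len(per_ref_stance_mean)
                and np.std(per_stance_mean) > 0
                and np.std(per_ref_stance_mean) > 0):
            r, cls = pearson_agreement(per_ref_stance_mean, per_stance_mean)
            summary.pearson_r, summary.pearson_class = r, cls
        report.methods[m] = summary

    report.matched_pairs = pd.DataFrame(
        pair_rows, columns=["participant", "method", "foot", "event_type",
                            "detected_s", "reference_s", "error_s"])
    report.stance_table = pd.DataFrame(
        stance_rows, columns=["participant", "method", "foot",
                              "heel_strike_s", "stance_s"])
    return report
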