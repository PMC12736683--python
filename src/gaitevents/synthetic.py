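"""Synthetic multi-modal gait trial generator with exact ground truth.

Generates co-registered vertical/antero-posterior ground reaction forces
(GRF), calcaneus and first-metatarsal marker trajectories, and sacral 3-axis
acceleration for a bilateral walking trial, together with the exact
heel-strike (HS) and toe-off (TO) times that produced them.  Every channel is
a documented closed-form function of the event times plus seeded additive
Gaussian noise, so detector accuracy can be measured against exact truth.

Signal construction (all closed forms; shape constants are module-level):

* **Vertical GRF** per stance of duration ``T``:
  ``F(u) = P * sqrt(sin(pi u)) * (1 - d * sin(pi u))`` with ``u = t/T``,
  ``P = GRF_PEAK_SCALE * body_weight`` and dip ``d = GRF_DIP``.  The square
  root rise makes the force cross a 15 N threshold within ~0.1 ms of the
  stance boundaries, and the crossing time solves a depressed cubic in
  ``sqrt(sin(pi u))`` (see :func:`vgrf_threshold_crossing`).  The two force
  peaks exceed body weight and the mid-stance valley dips below them
  (the physiological "M" shape).
* **Calcaneus vertical**: constant plateau in stance; a raised-cosine lift of
  height ``CAL_LIFT`` in early swing; a raised-cosine lowering of
  ``CAL_LIFT - CAL_DROP`` in late swing; and a final Gaussian-velocity drop
  of height ``CAL_DROP`` whose velocity pulse is centered *exactly* at the
  next HS — so the per-cycle minimum of vertical velocity is analytically at
  HS, which is what the foot-velocity detector keys on.
* **Metatarsal vertical**: Gaussian-velocity lift of height ``MET_LIFT``
  centered exactly at TO (per-cycle maximum of vertical velocity at TO),
  then a raised-cosine descent completing at the next HS.
* **AP marker position**: quiet in stance, advancing one stride length per
  swing with a smooth (zero-endpoint-velocity) raised-cosine velocity.
* **Sacral acceleration**: vertical axis is a superposition of per-step
  damped-oscillation impact transients starting at each HS
  (``A exp(-s/tau) sin(2 pi f s)``); the antero-posterior axis has one
  Gaussian bump per step centered a fixed lead ``ACC_AP_LEAD`` before the
  vertical peak, so the AP slope magnitude has its per-step minimum there.
  The analytic vertical-peak, first-trough and AP-flat times are recorded in
  :class:`SacralLandmarks` for detector testing.

Edge policy: an (HS, TO) pair is emitted as ground truth only when the
preceding toe-off is inside the trial and its own toe-off ends at least
``EDGE_GUARD`` before the trial ends, so every emitted event has full signal
context for the detectors; the signals themselves are built from an internal
event sequence extended beyond the trial so edge cycles look like interior
ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .errors import ConfigurationError, DomainError
from .events import GroundTruthEvents
from .imu import SacralAcc
from .omc import MarkerTrack
from .signal_prep import UniformSignal

__all__ = [
    "SyntheticConfig",
    "GaitTrial",
    "SacralLandmarks",
    "generate_trial",
    "vgrf_profile",
    "vgrf_threshold_crossing",
    "sacral_acc_profile",
    "calcaneus_vertical_position",
    "metatarsal_vertical_position",
]

# ---------------------------------------------------------------------------
# Shape constants (documented units).  These, together with the
# SyntheticConfig defaults, define the simulated walking conditions.
GRF_PEAK_SCALE = 2.1     # vertical GRF envelope scale, x body weight
GRF_DIP = 0.55           # mid-stance dip coefficient, dimensionless
APGRF_SCALE = 0.18       # AP braking/propulsion amplitude, x body weight

CAL_Z0 = 0.03            # calcaneus marker height in stance, m
CAL_LIFT = 0.10          # total calcaneus lift during swing, m
CAL_DROP = 0.04          # final landing drop (Gaussian velocity pulse), m
CAL_SIGMA = 0.015        # landing velocity-pulse width, s
CAL_RISE_FRAC = 0.5      # rise-ramp duration as fraction of swing

MET_Z0 = 0.02            # metatarsal marker height in stance, m
MET_LIFT = 0.05          # metatarsal lift at toe-off, m
MET_SIGMA = 0.02         # lift velocity-pulse width, s
MET_DESCENT_FRAC = 0.35  # descent-ramp start as fraction of swing

WALK_SPEED = 1.1         # forward progression speed, m/s
MET_AP_OFFSET = 0.15     # metatarsal ahead of calcaneus, m

ACC_AMP = 4.0            # vertical impact transient amplitude, m/s^2
ACC_FREQ = 5.0           # transient oscillation frequency, Hz
ACC_TAU = 0.08           # transient damping time constant, s
ACC_AP_AMP = 2.0         # AP bump amplitude, m/s^2
ACC_AP_SIGMA = 0.03      # AP bump width, s
ACC_AP_LEAD = 0.08       # AP flat-slope lead before vertical peak, s
ACC_ML_AMP = 0.8         # medio-lateral sway amplitude, m/s^2
ACC_ML_SIGMA = 0.05      # ML bump width, s
ACC_ML_DELAY = 0.20      # ML bump delay after HS, s

EDGE_GUARD = 0.15        # required trailing context after an emitted TO, s

# Named per-channel noise sub-streams: a single trial seed spawns one
# independent generator per entry via SeedSequence(seed).spawn-style keys.
CHANNEL_STREAMS = {
    "stride": 0,
    "vgrf_left": 1, "vgrf_right": 2, "apgrf_left": 3, "apgrf_right": 4,
    "cal_left_v": 5, "cal_left_ap": 6, "cal_right_v": 7, "cal_right_ap": 8,
    "met_left_v": 9, "met_left_ap": 10, "met_right_v": 11, "met_right_ap": 12,
    "acc_v": 13, "acc_ap": 14, "acc_ml": 15,
}


def _rng(seed: int, channel: str) -> np.random.Generator:
    """Deterministic per-channel stream derived from one trial seed."""
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(CHANNEL_STREAMS[channel],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SyntheticConfig:
    """Trial-generation parameters.

    Defaults encode the recording conditions this simulator emulates: 60 s
    overground walking trials, force plates at 1000 Hz, optical markers at
    100 Hz, a sacral accelerometer at 1259 Hz, stride period ~1.1 s with 2%
    stride-to-stride variability and a 62% stance fraction.
    """

    trial_duration: float = 60.0        # s
    stride_period_mean: float = 1.1     # s
    stride_period_cv: float = 0.02      # SD / mean, dimensionless
    stance_fraction: float = 0.62       # fraction of stride
    body_weight_force: float = 765.0    # N (~78 kg)
    noise_sd_grf: float = 2.0           # N
    noise_sd_marker: float = 0.0005     # m
    noise_sd_acc: float = 0.3           # m/s^2
    fs_grf: float = 1000.0              # Hz
    fs_marker: float = 100.0            # Hz
    fs_imu: float = 1259.0              # Hz
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.stance_fraction < 1, "0 < stance_fraction < 1"),
            (self.stride_period_mean > 0, "stride_period_mean > 0"),
            (self.fs_grf > 0 and self.fs_marker > 0 and self.fs_imu > 0,
             "all sampling rates > 0"),
            (self.stride_period_cv >= 0, "stride_period_cv >= 0"),
            (self.trial_duration >= 2 * self.stride_period_mean,
             "trial_duration >= 2 * stride_period_mean"),
            (self.body_weight_force > 0, "body_weight_force > 0"),
            (min(self.noise_sd_grf, self.noise_sd_marker, self.noise_sd_acc) >= 0,
             "noise standard deviations >= 0"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigurationError(f"invalid SyntheticConfig: requires {name}")


@dataclass(frozen=True)
class SacralLandmarks:
    """Analytic per-step landmark times of the sacral-acceleration model."""

    vertical_peaks: np.ndarray    # first positive peak after each HS, s
    vertical_troughs: np.ndarray  # first trough after each peak, s
    ap_flat_points: np.ndarray    # AP slope-magnitude minimum per step, s


@dataclass
class GaitTrial:
    """Synchronized multi-rate signal bundle for one walking trial."""

    vgrf_left: UniformSignal
    vgrf_right: UniformSignal
    apgrf_left: UniformSignal
    apgrf_right: UniformSignal
    calcaneus_left: MarkerTrack
    calcaneus_right: MarkerTrack
    metatarsal_left: MarkerTrack
    metatarsal_right: MarkerTrack
    sacral_acc: SacralAcc
    config: SyntheticConfig | None = None
    sacral_landmarks: SacralLandmarks | None = None
    trial_id: str = "trial"

    @property
    def duration(self) -> float:
        return self.vgrf_left.duration


# ---------------------------------------------------------------------------
# Closed-form profiles


def vgrf_profile(t_within_stance, stance_duration: float,
                 body_weight_force: float):
    """Vertical GRF at time ``t_within_stance`` into a stance.

    ``F(u) = P sqrt(sin(pi u)) (1 - d sin(pi u))`` with ``u`` the stance
    fraction, ``P = GRF_PEAK_SCALE * body_weight_force`` and ``d = GRF_DIP``.
    Zero at both boundaries, two peaks above body weight, one mid-stance
    valley.  Accepts scalars or arrays.
    """
    t = np.asarray(t_within_stance, dtype=float)
    if np.any(t < 0) or np.any(t > stance_duration):
        raise DomainError("t_within_stance must lie in [0, stance_duration]")
    s = np.sin(np.pi * t / stance_duration)
    out = GRF_PEAK_SCALE * body_weight_force * np.sqrt(s) * (1.0 - GRF_DIP * s)
    out = np.where((t == 0.0) | (t == stance_duration), 0.0, out)
    return float(out) if np.isscalar(t_within_stance) else out


def vgrf_threshold_crossing(threshold: float, stance_duration: float,
                            body_weight_force: float) -> float:
    """Time after stance onset at which the noise-free vertical GRF first
    reaches ``threshold`` N (exact inversion of :func:`vgrf_profile` on the
    rising edge; by symmetry the force falls through the same level
    ``stance_duration - dt`` after onset)."""
    p = GRF_PEAK_SCALE * body_weight_force
    r = threshold / p
    if not 0 < r < 1:
        raise DomainError("threshold must be positive and below the peak force")
    # q = sqrt(sin(pi u)) solves q (1 - d q^2) = r; bracket on the rising edge.
    q_peak = 1.0 / math.sqrt(3.0 * GRF_DIP)
    q = brentq(lambda q_: q_ * (1.0 - GRF_DIP * q_ ** 2) - r, 0.0, q_peak,
               xtol=1e-15)
    u = math.asin(min(q * q, 1.0)) / math.pi
    return u * stance_duration


def _ramp(x):
    """Normalized raised-cosine-velocity ramp: 0 -> 1 over x in [0, 1]."""
    xc = np.clip(x, 0.0, 1.0)
    return xc - np.sin(2.0 * np.pi * xc) / (2.0 * np.pi)


def _norm_cdf(x):
    return 0.5 * (1.0 + erf(np.asarray(x, dtype=float) / math.sqrt(2.0)))


class _FootKinematics:
    """Closed-form marker trajectory evaluator for one foot.

    ``hs`` and ``to`` are the *internal* event sequences (extended beyond the
    trial limits) with ``len(hs) == len(to)`` and ``hs[i] < to[i] < hs[i+1]``.
    All methods accept arbitrary time arrays, which the test suite uses to
    finite-difference the closed forms densely.
    """

    def __init__(self, hs: np.ndarray, to: np.ndarray, ap_origin: float = 0.0):
        if len(hs) != len(to) or len(hs) < 2:
            raise ConfigurationError("need >= 2 (HS, TO) pairs per foot")
        self.hs = np.asarray(hs, dtype=float)
        self.to = np.asarray(to, dtype=float)
        self.ap_origin = ap_origin
        self.stride = np.diff(self.hs)
        # cumulative AP advance at the start of each cycle
        adv = WALK_SPEED * self.stride
        self.ap_cum = np.concatenate([[0.0], np.cumsum(adv)])

    def _cycle_index(self, t):
        idx = np.searchsorted(self.hs, t, side="right") - 1
        return np.clip(idx, 0, len(self.hs) - 2)

    def calcaneus_vertical(self, t):
        t = np.asarray(t, dtype=float)
        i = self._cycle_index(t)
        hs0, hs1, to0 = self.hs[i], self.hs[i + 1], self.to[i]
        tsw = hs1 - to0
        t_rise = CAL_RISE_FRAC * tsw
        t_f0 = to0 + t_rise
        t_f = (hs1 - 3.0 * CAL_SIGMA) - t_f0
        z = (CAL_Z0
             + CAL_LIFT * _ramp((t - to0) / t_rise)
             - (CAL_LIFT - CAL_DROP) * _ramp((t - t_f0) / t_f)
             - CAL_DROP * _norm_cdf((t - hs1) / CAL_SIGMA)
             + CAL_DROP * _norm_cdf(-(t - hs0) / CAL_SIGMA))
        return z

    def metatarsal_vertical(self, t):
        t = np.asarray(t, dtype=float)
        i = self._cycle_index(t)
        hs1, to0 = self.hs[i + 1], self.to[i]
        tsw = hs1 - to0
        t_d0 = to0 + MET_DESCENT_FRAC * tsw
        t_d = hs1 - t_d0
        z = (MET_Z0
             + MET_LIFT * _norm_cdf((t - to0) / MET_SIGMA)
             - MET_LIFT * _ramp((t - t_d0) / t_d))
        return z

    def ap_position(self, t, offset: float = 0.0):
        t = np.asarray(t, dtype=float)
        i = self._cycle_index(t)
        hs1, to0 = self.hs[i + 1], self.to[i]
        tsw = hs1 - to0
        adv = WALK_SPEED * (hs1 - self.hs[i])
        return self.ap_origin + offset + self.ap_cum[i] + adv * _ramp((t - to0) / tsw)

    def vgrf(self, t, body_weight: float):
        t = np.asarray(t, dtype=float)
        i = self._cycle_index(t)
        hs0, to0 = self.hs[i], self.to[i]
        stance = to0 - hs0
        u = (t - hs0) / stance
        inside = (u >= 0.0) & (u <= 1.0)
        s = np.sin(np.pi * np.clip(u, 0.0, 1.0))
        f = GRF_PEAK_SCALE * body_weight * np.sqrt(s) * (1.0 - GRF_DIP * s)
        return np.where(inside, f, 0.0)

    def apgrf(self, t, body_weight: float):
        t = np.asarray(t, dtype=float)
        i = self._cycle_index(t)
        hs0, to0 = self.hs[i], self.to[i]
        stance = to0 - hs0
        u = (t - hs0) / stance
        inside = (u >= 0.0) & (u <= 1.0)
        uc = np.clip(u, 0.0, 1.0)
        f = -APGRF_SCALE * body_weight * np.sin(2.0 * np.pi * uc) * np.sin(np.pi * uc)
        return np.where(inside, f, 0.0)


def calcaneus_vertical_position(t, hs, to):
    """Closed-form calcaneus vertical trajectory for internal events
    ``hs``/``to`` (module-level convenience wrapper used by the tests)."""
    return _FootKinematics(np.asarray(hs), np.asarray(to)).calcaneus_vertical(t)


def metatarsal_vertical_position(t, hs, to):
    """Closed-form metatarsal vertical trajectory (see above)."""
    return _FootKinematics(np.asarray(hs), np.asarray(to)).metatarsal_vertical(t)


# ---------------------------------------------------------------------------
# Sacral acceleration

_OMEGA = 2.0 * math.pi * ACC_FREQ
#: analytic offset from HS to the first positive peak of the impact transient
S_PEAK = math.atan(_OMEGA * ACC_TAU) / _OMEGA
#: analytic offset from HS to the first trough (next extremum of the template)
S_TROUGH = (math.atan(_OMEGA * ACC_TAU) + math.pi) / _OMEGA


def _impact_template(s):
    """Damped-oscillation vertical impact transient, zero before s = 0."""
    s = np.asarray(s, dtype=float)
    out = ACC_AMP * np.exp(-np.maximum(s, 0.0) / ACC_TAU) * np.sin(_OMEGA * np.maximum(s, 0.0))
    return np.where(s >= 0.0, out, 0.0)


def sacral_acc_profile(step_times: np.ndarray, t: np.ndarray,
                       step_feet: np.ndarray | None = None):
    """Noise-free sacral acceleration axes evaluated at times ``t``.

    ``step_times`` are the HS times of *both* feet merged (one transient per
    step); ``step_feet`` optionally gives each step's side (+1 left / -1
    right) to alternate the medio-lateral sway sign.  Returns
    ``(vertical, ap, ml, landmarks)``; an empty step list yields flat
    zero-mean signals.
    """
    t = np.asarray(t, dtype=float)
    step_times = np.asarray(step_times, dtype=float)
    vert = np.zeros_like(t)
    ap = np.zeros_like(t)
    ml = np.zeros_like(t)
    if step_times.size == 0:
        empty = np.array([])
        return vert, ap, ml, SacralLandmarks(empty, empty, empty)
    if step_feet is None:
        step_feet = np.where(np.arange(step_times.size) % 2 == 0, 1.0, -1.0)
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    support = max(5.0 * ACC_TAU, 1.0 / ACC_FREQ)
    for hs, side in zip(step_times, step_feet):
        lo = int(np.floor((hs - 5.0 * ACC_AP_SIGMA - ACC_AP_LEAD - t[0]) / dt))
        hi = int(np.ceil((hs + support + 5.0 * ACC_ML_SIGMA + ACC_ML_DELAY - t[0]) / dt)) + 1
        lo, hi = max(lo, 0), min(hi, t.size)
        if lo >= hi:
            continue
        s = t[lo:hi] - hs
        vert[lo:hi] += _impact_template(s)
        c_ap = S_PEAK - ACC_AP_LEAD
        ap[lo:hi] += ACC_AP_AMP * np.exp(-((s - c_ap) ** 2) / (2.0 * ACC_AP_SIGMA ** 2))
        ml[lo:hi] += side * ACC_ML_AMP * np.exp(
            -((s - ACC_ML_DELAY) ** 2) / (2.0 * ACC_ML_SIGMA ** 2))
    landmarks = SacralLandmarks(
        vertical_peaks=step_times + S_PEAK,
        vertical_troughs=step_times + S_TROUGH,
        ap_flat_points=step_times + S_PEAK - ACC_AP_LEAD,
    )
    return vert, ap, ml, landmarks


# ---------------------------------------------------------------------------
# Trial generation


def _internal_events(config: SyntheticConfig, rng: np.random.Generator):
    """Internal (extended) HS/TO sequences per foot.

    The left-foot heel strikes accumulate seeded stride periods starting two
    mean strides before t = 0 and ending two mean strides after the trial;
    the right foot is offset by half of each stride.
    """
    mean, cv = config.stride_period_mean, config.stride_period_cv
    start = -2.0 * mean
    horizon = config.trial_duration + 2.0 * mean
    hs_left = [start]
    strides = []
    while hs_left[-1] < horizon:
        tk = mean * (1.0 + cv * float(rng.standard_normal()))
        tk = float(np.clip(tk, 0.5 * mean, 1.5 * mean))
        strides.append(tk)
        hs_left.append(hs_left[-1] + tk)
    hs_left = np.array(hs_left)
    strides = np.array(strides)
    hs_right = hs_left[:-1] + 0.5 * strides
    # stance of each cycle scales with that cycle's stride
    stance_left = config.stance_fraction * np.concatenate([strides, strides[-1:]])
    stance_right = config.stance_fraction * strides
    to_left = hs_left + stance_left
    to_right = hs_right + stance_right
    return (hs_left, to_left), (hs_right, to_right)


def _emit_truth(hs: np.ndarray, to: np.ndarray, duration: float):
    """Apply the edge policy: keep pair i iff TO_{i-1} >= 0 and
    TO_i <= duration - EDGE_GUARD (full preceding stance + swing context and
    trailing context inside the trial)."""
    keep = []
    for i in range(1, len(hs)):
        if to[i - 1] >= 0.0 and to[i] <= duration - EDGE_GUARD:
            keep.append(i)
    return [float(hs[i]) for i in keep], [float(to[i]) for i in keep]


def generate_trial(config: SyntheticConfig,
                   trial_id: str = "trial") -> tuple[GaitTrial, GroundTruthEvents]:
    """Generate one synthetic walking trial and its exact ground truth.

    Identical ``config`` (including ``rng_seed``) produces bit-identical
    signals and event lists.
    """
    if not isinstance(config, SyntheticConfig):
        config = SyntheticConfig(**config)  # raises ConfigurationError if invalid

    stride_rng = _rng(config.rng_seed, "stride")
    (hs_l, to_l), (hs_r, to_r) = _internal_events(config, stride_rng)

    d = config.trial_duration
    truth = GroundTruthEvents(*_emit_truth(hs_l, to_l, d),
                              *_emit_truth(hs_r, to_r, d))

    left = _FootKinematics(hs_l, to_l, ap_origin=0.0)
    right = _FootKinematics(hs_r, to_r, ap_origin=0.55 * WALK_SPEED * config.stride_period_mean)

    def noisy(x, sd, channel):
        if sd == 0:
            return x
        return x + sd * _rng(config.rng_seed, channel).standard_normal(x.size)

    # --- force plates -----------------------------------------------------
    t_grf = np.arange(int(round(d * config.fs_grf)) + 1) / config.fs_grf
    bw = config.body_weight_force
    vgrf = {}
    apgrf = {}
    for name, foot in (("left", left), ("right", right)):
        vgrf[name] = UniformSignal(
            noisy(foot.vgrf(t_grf, bw), config.noise_sd_grf, f"vgrf_{name}"),
            config.fs_grf, 0.0, f"vgrf_{name}")
        apgrf[name] = UniformSignal(
            noisy(foot.apgrf(t_grf, bw), config.noise_sd_grf, f"apgrf_{name}"),
            config.fs_grf, 0.0, f"apgrf_{name}")

    # --- optical markers --------------------------------------------------
    t_mk = np.arange(int(round(d * config.fs_marker)) + 1) / config.fs_marker

    def track(foot, name, kind):
        if kind == "cal":
            vert = foot.calcaneus_vertical(t_mk)
            ap = foot.ap_position(t_mk)
        else:
            vert = foot.metatarsal_vertical(t_mk)
            ap = foot.ap_position(t_mk, offset=MET_AP_OFFSET)
        sd = config.noise_sd_marker
        marker = "calcaneus" if kind == "cal" else "metatarsal_1"
        return MarkerTrack(
            vertical=UniformSignal(noisy(vert, sd, f"{kind}_{name}_v"),
                                   config.fs_marker, 0.0, f"{kind}_{name}_v"),
            anteroposterior=UniformSignal(noisy(ap, sd, f"{kind}_{name}_ap"),
                                          config.fs_marker, 0.0, f"{kind}_{name}_ap"),
            marker=marker, foot=name)

    cal_l, cal_r = track(left, "left", "cal"), track(right, "right", "cal")
    met_l, met_r = track(left, "left", "met"), track(right, "right", "met")

    # --- sacral accelerometer --------------------------------------------
    t_imu = np.arange(int(round(d * config.fs_imu)) + 1) / config.fs_imu
    steps = np.concatenate([hs_l, hs_r])
    feet = np.concatenate([np.ones(hs_l.size), -np.ones(hs_r.size)])
    order = np.argsort(steps)
    vert, ap, ml, _ = sacral_acc_profile(steps[order], t_imu, feet[order])
    # landmarks restricted to in-trial steps, for detector testing
    in_trial = (steps[order] >= 0.0) & (steps[order] + S_TROUGH <= d)
    landmarks = SacralLandmarks(
        vertical_peaks=steps[order][in_trial] + S_PEAK,
        vertical_troughs=steps[order][in_trial] + S_TROUGH,
        ap_flat_points=steps[order][in_trial] + S_PEAK - ACC_AP_LEAD,
    )
    acc = SacralAcc(
        vertical=UniformSignal(noisy(vert, config.noise_sd_acc, "acc_v"),
                               config.fs_imu, 0.0, "acc_vertical"),
        anteroposterior=UniformSignal(noisy(ap, config.noise_sd_acc, "acc_ap"),
                                      config.fs_imu, 0.0, "acc_ap"),
        mediolateral=UniformSignal(noisy(ml, config.noise_sd_acc, "acc_ml"),
                                   config.fs_imu, 0.0, "acc_ml"),
    )

    trial = GaitTrial(
        vgrf_left=vgrf["left"], vgrf_right=vgrf["right"],
        apgrf_left=apgrf["left"], apgrf_right=apgrf["right"],
        calcaneus_left=cal_l, calcaneus_right=cal_r,
        metatarsal_left=met_l, metatarsal_right=met_r,
        sacral_acc=acc, config=config, sacral_landmarks=landmarks,
        trial_id=trial_id,
    )
    return trial, truth
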