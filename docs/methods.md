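# Methods

This note documents the models and numerical choices behind `gaitevents`:
what the synthetic gait simulator generates and why, how each detector is
parameterized, and what the statistics layer computes. It is the place to
look when a default needs justifying or a degenerate case needs explaining.

## The synthetic gait model

Real validation studies of gait event detection compare detectors against
force-plate events on walking data that are rarely shared. The simulator
replaces the laboratory: it emits co-registered force, marker and
acceleration channels as *documented closed-form functions of the true
event times*, plus the event times themselves, so detector error is
measurable exactly.

### Timing skeleton

Left-foot heel strikes accumulate stride periods drawn i.i.d. from
N(mean, (cv·mean)²), truncated to ±50 % of the mean; the right foot is
offset by half of each stride (symmetric gait). Stance duration is a fixed
fraction of the cycle's own stride. Defaults: stride 1.1 s, cv 2 %, stance
fraction 0.62, 60 s trials — conventional values for healthy adults at
preferred speed. The internal event sequence extends two strides beyond the
trial on both sides so edge cycles look like interior ones; a ground-truth
pair (HS, TO) is *emitted* only when the preceding toe-off is inside the
trial and its own toe-off ends ≥ 0.15 s before the end, guaranteeing each
emitted event has full signal context (detectors may legitimately find a
few extra events in the unemitted edge cycles).

### Channels (closed forms)

* **Vertical GRF** per stance of duration *T*, with u = t/T:
  F(u) = 2.1·BW·√(sin πu)·(1 − 0.55·sin πu). The square-root rise crosses a
  15 N threshold ≈ 0.06 ms after contact (well within one 1 kHz sample); the
  crossing time is exactly invertible via a cubic in √(sin πu)
  (`vgrf_threshold_crossing`). Two peaks ≈ 1.09·BW bracket a mid-stance
  valley ≈ 0.94·BW — the physiological "M" shape. A raised-cosine hump pair
  was considered first but rises only quadratically from zero and cannot
  reach the threshold within a sample at realistic amplitudes, which would
  make the gold standard systematically late; the square-root envelope was
  adopted instead. AP force is a braking/propulsion couple
  −0.18·BW·sin(2πu)·sin(πu).
* **Calcaneus vertical**: constant plateau in stance; raised-cosine lift
  (0.10 m) in early swing; raised-cosine lowering in late swing; and a final
  0.04 m drop whose *velocity* is a Gaussian pulse (σ = 15 ms) centred
  exactly on the next heel strike. The per-cycle velocity minimum therefore
  sits analytically *at* the heel strike with symmetric curvature, so
  zero-phase 15 Hz filtering does not displace it — this is what makes the
  foot-velocity detector's reference behaviour testable to a few ms. A
  one-sided cosine-arc landing was rejected because filtering shifts a
  boundary-kink extremum by ~30 ms.
* **Metatarsal vertical**: mirrored — a Gaussian-velocity lift (0.05 m,
  σ = 20 ms) centred exactly on toe-off, then a raised-cosine descent
  completing at the next heel strike.
* **AP marker position**: quiet in stance; advances 1.1 m/s × stride per
  swing with a zero-endpoint-velocity raised-cosine profile. The quiet
  stance phase is what the adaptive-threshold detector's stationary window
  measures.
* **Sacral acceleration**: the vertical axis superimposes one damped
  oscillation A·e^(−s/τ)·sin(2πf s) per step (A = 4 m/s², f = 5 Hz,
  τ = 80 ms) starting at each heel strike of either foot. Its first positive
  peak is analytically at s\* = atan(2πfτ)/2πf ≈ 38 ms and its first trough
  at s\* + 100 ms — inside the 0.15 s refinement window the hierarchical
  detector assumes, and, at the default timing, essentially coincident with
  the contralateral toe-off (double support ≈ 0.13 s), mirroring how sacral
  troughs relate to real gait events. The AP axis has one Gaussian bump per
  step centred 80 ms before the vertical peak, so |d(AP)/dt| has its
  per-step minimum there; the medio-lateral axis is a small alternating-sign
  sway. The analytic peak/trough/flat-point times are exposed as
  `SacralLandmarks` for testing.

### Noise and seeding

All noise is additive i.i.d. Gaussian per channel (no soft-tissue artifact,
no baseline drift): defaults 2 N (force), 0.5 mm (markers), 0.3 m/s²
(acceleration). One integer seed derives an independent, named sub-stream
per channel via `SeedSequence(seed, spawn_key=(code,))`, so regenerating one
channel never perturbs another and identical configs are bit-identical.

### What the simulator does not emulate

No forward dynamics, no medio-lateral force realism, no soft-tissue marker
wobble, no turning or treadmill gait, no pathological patterns, no
left/right asymmetry beyond the half-stride offset. Consequently detector
errors here are *cleaner* than on real data: passing tests shows the
algorithms implement their rules correctly and respond to noise and timing
jitter sensibly, not that their absolute accuracies match any particular
population.

## Detector parameterization

* **GRF** (gold standard): 15 N on raw force; first sample ≥ threshold is
  HS, first sample below after a stance is TO. Debounce: sub-threshold gaps
  < 50 ms merged, supra-threshold runs < 100 ms discarded — far below
  physiological stance/swing, present only because raw thresholding
  chatters on noise. Runs touching the record ends are dropped.
* **OMC1**: markers linearly interpolated to 1000 Hz, 4th-order zero-phase
  Butterworth at 15 Hz, central-difference velocity. Qualifying extrema need
  prominence ≥ 10 % of the velocity's 2nd–98th inter-percentile range
  (quartiles collapse onto the noise floor for signals quiet 60 % of the
  time) and separation ≥ 0.4 × the dominant cycle period.
* **OMC2**: 10 Hz filtering; sagittal speed = √(v_vert² + v_AP²); cycle
  anchors at per-stance minima of the box-smoothed (0.25 s) heel speed,
  including head/tail anchors when a quiet region is visible at the record
  ends, plus a virtual end boundary so the final cycle is scanned.
  Stationary windows: 50 ms (HS) and 75 ms (TO, lengthened to absorb
  pre-lift micro-movement) centred on the quiet-phase speed minimum;
  threshold = window mean + 1·SD (multiplier configurable). Crossings are
  debounced: the mean speed over the next 25 ms must sit on the triggering
  side — a plateau whose samples straddle a mean+SD threshold still
  triggers at its onset, while isolated noise blips cannot. A perfectly
  flat, noise-free window yields a zero threshold and raises
  `DegenerateThresholdError`; the pipeline therefore floors the threshold at
  0.05 m/s, the classic fixed sagittal-speed threshold from which the
  adaptive variant descends. The floor also keeps the effective threshold
  — hence the detector's bias — constant across noise levels instead of
  tracking the noise floor.
* **IMU1**: polyphase 1259→1000 Hz downsampling, 30 Hz zero-phase low-pass,
  vertical mean removal, trapezoidal integration (no drift correction — the
  integral is used only as a low-pass step), then two single-scale
  continuous wavelet transforms with a first-derivative-of-Gaussian
  ("gaus1") kernel, implemented as direct convolution with reflect padding;
  the sign convention makes a rising input produce positive output. Default
  scale = fs/(10·f_dom), with f_dom the step rate from the first
  autocorrelation peak of the vertical acceleration — an FFT-peak estimate
  is bimodal on impact-like signals (the power can sit on the first
  harmonic) and made the scale, and hence the detector's bias, flip between
  trials.
* **IMU2**: per-axis mean subtraction, 5th-order median filter, max-abs
  normalization. Anchors: positive vertical maxima ≥ 0.3 (normalized),
  greedily accepted in descending amplitude with ≥ 0.35 s separation; the
  height floor encodes that coarse anchors are the *dominant* step peaks,
  without which any positive noise wiggle in an inter-step gap can anchor a
  spurious cycle. Toe-off = first local minimum with negative value in
  (anchor, anchor + 0.15 s]; heel strike = argmin of |d(AP)/dt| in
  [anchor − 0.15 s, anchor). Windows are half-open so boundary behaviour is
  deterministic. The documented alternative heel-strike anchor (largest
  positive AP peak of the step) is not implemented.

Both IMU methods return `foot="unassigned"`; the evaluation layer matches
them against the two feet's reference events merged.

## Evaluation layer

Matching is greedy one-to-one nearest-neighbour in ascending |error| with
tolerance = 0.5 × the reference's median stride (for merged references the
stride is twice the median event spacing) — wide enough for biased
detectors, narrow enough to forbid cross-stride pairing. Stance is heel
strike → next toe-off; for side-agnostic series the pairing skips one event,
because the next toe-off after a heel strike belongs to the contralateral
foot (double support), and the alternation of merged events makes the
skip-one rule recover same-side stance. A config switch (`literal_swing`)
computes toe-off → next heel strike instead. All SDs are sample (n−1) SDs.
RMSE and error range are computed per participant and averaged;
Bland–Altman pools matched stance pairs across participants; Pearson r uses
one point per participant (their mean stance time), which is why the
pipeline perturbs each synthetic participant's mean stride by 5 % — without
between-subject variance the correlation is undefined. Correlations in the
band (0.3, 0.4], which the classification scheme leaves undefined, are
labelled `"unclassified-gap"` rather than silently binned.

## Problem sizes and determinism

The shipped studies use 60 s trials (≈ 50 strides per foot), 17 synthetic
participants × 2 trials for the cohort summaries, 20-seed replicates at
three noise levels (0×, 1×, 4× the default SDs) for the noise-sensitivity
check, and 20 s trials where a single trial suffices. Event tables and
reports serialize times as decimal seconds with six fractional digits, so
repeated runs with the same config and seed are byte-identical; write/read
round-trips are exact at that 10⁻⁶ s grain.

## Known limitations

* Detector accuracies on this simulator reflect its idealized geometry; the
  marker detectors in particular are more accurate here than on real data
  because there is no soft-tissue artifact.
* IMU1's large systematic offset (~0.18 s) is a property of the sacral
  template and the smoothing scale: its S1 extrema lock to a fixed phase of
  the step cycle, not to the impact transient itself. The offset is stable
  (constant sign, small spread), which is the behaviour the validation
  statistics are designed to expose.
* The simulator's stance fraction is constant within a trial; stance-time
  variability therefore comes only from stride-period variability and
  detection error.
* OMC2 requires either measurable stationary-phase noise or an explicit
  threshold floor; it has no fallback when a cycle contains no threshold
  crossing (the cycle is skipped with a warning).
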