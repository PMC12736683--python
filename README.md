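# gaitevents

Gait event detection and method validation for human walking.

The instants of heel strike (i-HS) and toe-off (i-TO) segment walking into
gait cycles; their timing underpins stride, stance and swing durations and
the gait-cycle segmentation of biosignals such as EMG and EEG. The gold
standard localizes them from the vertical ground reaction force (GRF)
crossing a small force threshold, but force plates are expensive and
confined to the lab. This package implements, in one tested codebase, the
gold standard plus four widely used alternatives — two optical-motion-capture
(OMC) detectors working from calcaneus and first-metatarsal markers and two
detectors working from a single sacrum-mounted accelerometer (IMU) — together
with the statistics used to validate them (timing RMSE, error range,
stance-time coefficient of variation, Bland–Altman limits of agreement,
Pearson agreement), and a synthetic multi-modal gait simulator with *exact*
ground-truth event times so the whole pipeline is testable end to end
without laboratory data.

It is intended for movement scientists who want a reproducible reference
implementation of these detectors, and for anyone studying how detector
errors propagate into derived gait parameters.

## Methods implemented

| Method | Signal | Rule |
|---|---|---|
| `grf`  | vertical GRF, 1000 Hz, raw | i-HS / i-TO at crossings of a 15 N threshold (debounced) |
| `omc1` | marker vertical velocity (15 Hz low-pass) | i-HS = minima of calcaneus vertical velocity; i-TO = maxima of metatarsal vertical velocity |
| `omc2` | marker sagittal speed (10 Hz low-pass) | per-step threshold = mean + SD of speed in a stationary-contact window (50 ms for i-HS, 75 ms for i-TO); i-HS when heel speed falls below it, i-TO when metatarsal speed exceeds it |
| `imu1` | sacral vertical acceleration (30 Hz low-pass) | trapezoidal integration, then two Gaussian-wavelet (gaus1) differentiations: i-HS = minima of S1, i-TO = maxima of S2 |
| `imu2` | sacral vertical + AP acceleration (normalized) | coarse vertical peaks (≥ 0.35 s apart); i-TO = first negative trough within 0.15 s after the peak; i-HS = minimum of \|d(AP)/dt\| within 0.15 s before it |

The evaluation layer matches detected to reference events one-to-one
(greedy nearest-neighbour within half a stride), and reports per event type
the root-mean-square error and the range of signed errors; per method the
stance time (i-HS → next i-TO), its intra-subject variability
ISV = SD/mean × 100, Bland–Altman mean difference with 95 % limits of
agreement (mean ± 1.96 SD of paired differences), and the Pearson r of
per-participant mean stance times classified as low (r ≤ 0.3), moderate
(0.4 < r ≤ 0.6) or high (r > 0.6).

## Worked example

```python
from gaitevents import SyntheticConfig, generate_trial
from gaitevents.pipeline import RunConfig, detect_with_method
from gaitevents.evaluation import match_events, default_tolerance, rmse, stance_times, isv

cfg = SyntheticConfig(trial_duration=60.0, rng_seed=1)
trial, truth = generate_trial(cfg)          # signals + exact event times
rc = RunConfig()
print(f"simulated {truth.n_steps} steps in {cfg.trial_duration:.0f} s")
for method in ("grf", "omc1", "imu2"):
    errs, stances = [], []
    for series in detect_with_method(method, trial, rc):
        ref = (truth.merged_series() if series.foot == "unassigned"
               else truth.series(series.foot))
        hs, to = match_events(series, ref, default_tolerance(ref))
        errs += hs.errors.tolist() + to.errors.tolist()
        stances += stance_times(series).stance_times
    print(f"{method}: RMSE {1e3*rmse(errs):5.1f} ms, stance ISV {isv(stances):4.2f} %")
```

prints

```
simulated 108 steps in 60 s
grf: RMSE   0.6 ms, stance ISV 1.97 %
omc1: RMSE   0.6 ms, stance ISV 1.97 %
imu2: RMSE  42.1 ms, stance ISV 3.98 %
```

The force detector recovers the simulator's ground truth to sub-millisecond
accuracy (it sees the same physics that generated the events); the
foot-velocity method is nearly as exact on clean marker data, while the
sacral-accelerometer method carries a tens-of-milliseconds systematic offset
— mechanical propagation from foot to sacrum — and a visibly larger
stance-time variability, the qualitative pattern these methods show on real
walking data.

A command-line interface mirrors the library:

```sh
gaitevents simulate --out trial/ --seed 7        # one trial + manifest + truth
gaitevents detect --trial trial/ --method omc1 --out events.tsv
gaitevents run --out study/ --seed 42            # full cohort study + report.json
```

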