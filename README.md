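# fatiguekit

Driver-fatigue detection from facial-landmark video streams.

Drowsiness shows in the face before it shows in the driving: eye
closures lengthen, yawns appear, and the percentage of eyelid-closed
time (PERCLOS) climbs. `fatiguekit` turns a per-frame 68-point facial
landmark stream (from any pretrained detector backend, or from the
built-in simulator) into per-window fatigue decisions. It is aimed at
researchers and engineers prototyping camera-based driver-monitoring
pipelines who need the feature extraction, classification and temporal
decision logic without committing to a particular face detector.

## What it computes

**Per-frame openness.** The eye aspect ratio
`EAR = (‖P2−P6‖ + ‖P3−P5‖) / (2‖P1−P4‖)` over the six eye landmarks,
and the analogous mouth aspect ratio MAR. Eyes count closed when
`EAR ≤ 0.21`, the mouth open when `MAR > 0.4`. An image-processing EAR
variant is also provided for when landmarks are unreliable: crop the
eye region, denoise, Otsu-binarize (eye pixels → 255), correct the eye
tilt, and take `EAR = H/W` with height `H = M/255` from the maximum
per-column gray sum `M` and width `W` from the eye corners.

**Per-window features.** Over each detection window (default 60 s):
longest continuous eye closure `F_t` (seconds), yawn count (mouth-open
runs ≥ 4 s), and frame-ratio PERCLOS `F_p`. A P80 PERCLOS on a
continuous closure signal is included for completeness.

**Classification.** A small back-propagation network (3 inputs → one
hidden layer, default 4 logistic units → 1 logistic output) trained
with binary cross-entropy and Adam (batch 8, 4000 epochs, 90/10
train/validation split), with z-scored inputs.

**Time accumulation.** The core decision rule: each window is split
into `n > 1` segments, each segment classified 0/1, and the states
pooled into the cumulative fatigue value

```
a_F = (1/n) Σ_i [ x_i·σ(x_i) − (1−x_i)·σ(x_i) ],    σ(x) = 1/(1+e^(−x))
```

which takes one of `n+1` evenly spaced levels between −0.5 and
σ(1) ≈ 0.731 depending only on the fatigue-segment count `k`. The
operating threshold θ_F is calibrated over the midpoints of adjacent
levels; with the defaults (`n = 3`, `θ_F = 0.116`) a window is fatigued
iff at least 2 of its 3 segments are — so a single smiling/speaking
episode that masquerades as an eye closure no longer flags the window.

## Worked example

```python
import numpy as np
from fatiguekit import (SegmentDecisions, cumulative_levels,
                        candidate_thresholds, decide_window)

print(np.round(cumulative_levels(3), 3))
# [-0.5   -0.09   0.321  0.731]   <- attainable a_F for k = 0..3
print(np.round(candidate_thresholds(3), 3))
# [-0.295  0.116  0.526]          <- candidate thresholds (midpoints)

res = decide_window(SegmentDecisions((1, 0, 0)), theta=0.116)
print(round(res.a_f, 3), res.state)
# -0.09 awake   <- one noisy fatigue segment is filtered out
res = decide_window(SegmentDecisions((1, 1, 0)), theta=0.116)
print(round(res.a_f, 3), res.state)
# 0.321 fatigue <- two of three segments fatigued flags the window
```

End-to-end on simulated video via the CLI:

```bash
fatiguekit simulate --duration 360 --fatigue-from 180 --seed 2 --out-prefix sim
fatiguekit extract  --landmarks sim_landmarks.csv --out obs.csv
fatiguekit features --observations obs.csv --out feats.csv
# join labels from sim_labels.csv onto feats.csv, then:
fatiguekit train    --features feats.csv --out model.json
fatiguekit detect   --landmarks sim_landmarks.csv --model model.json \
                    --mode cumulative --out states.csv
```

`states.csv` holds one row per window: `window_id, start_s, end_s,
state (0 awake / 1 fatigue), k, a_F, theta` — the trace you would plot
against time to locate the awake→fatigue transition.

## Layout

| module | contents |
| --- | --- |
| `fatiguekit.tracking` | Kalman face-box tracker (constant-velocity, gap filling) |
| `fatiguekit.landmarks` | EAR / MAR / image-processing EAR, frame states, threshold sweep |
| `fatiguekit.temporal` | windowing, longest closure, yawns, PERCLOS |
| `fatiguekit.classifier` | 3-m-1 BP network, hidden-node sizing, serialization |
| `fatiguekit.accumulation` | cumulative fatigue value, levels, thresholds, calibration |
| `fatiguekit.synthetic` | rendered eye images, landmark streams, labeled window sets |
| `fatiguekit.io`, `.pipeline`, `.cli` | CSV/JSON schemas, pipeline runners, CLI |

See `docs/methods.md` for the modelling details and design choices.
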