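# Methods

## Problem and pipeline

Camera-based driver-monitoring infers drowsiness from facial behavior.
The pipeline here consumes a per-frame 68-point landmark stream
(produced by any pretrained face/landmark backend; face detection and
landmark regression are deliberately out of scope) and proceeds in four
stages: per-frame openness ratios, binary eye/mouth states, windowed
temporal features, and a per-window decision. Two decision rules are
implemented — a whole-window classifier and a segment-wise
time-accumulation rule — so their behavior under expression noise can
be compared on identical input.

## Per-frame measurements

The eye aspect ratio `EAR = (‖P2−P6‖+‖P3−P5‖)/(2‖P1−P4‖)` is a
similarity invariant of the six eye landmarks; the mouth aspect ratio
is the same functional on the mouth landmarks. Landmark indices follow
the iBUG-68 convention (right eye 36–41, left eye 42–47, mouth corners
48/54, upper lip 50/52, lower lip 58/56); the per-frame EAR is the
mean of the two eyes (a documented choice — one could equally use a
single eye). Eyes count closed when `EAR ≤ 0.21` and the mouth open
when `MAR > 0.4`; equality at the threshold counts closed in both
cases ("open" must strictly exceed the threshold). Both defaults are
calibration outcomes of an accuracy sweep (`sweep_threshold`), which
scans a grid, scores `value > t` against labels, and returns the
smallest maximizer.

The image-processing EAR replaces the lid-landmark distances, which
degrade under dim light or deep eye sockets, with a pixel measurement:
crop the bounding box of the four lid landmarks extended by 50% of its
height both up and down, Gaussian-denoise (σ = 1 px, configurable),
Otsu-binarize, map the eye class to 255, rotate the crop by the
negative of the P1→P4 axis angle (bilinear, expanded canvas), and set
`H = max column sum / 255`, `W = ‖P1−P4‖`, `EAR = H/W`. Otsu polarity
defaults to "auto": the minority pixel class of the extended crop is
taken as the eye region, which is correct both for dark iris/lash
pixels against skin and for the bright-on-dark synthetic fixtures;
"dark"/"bright" force a polarity. A featureless (constant) crop yields
EAR 0 rather than an error. On rendered ellipse eyes with aspect
ratios 0.05–0.5 and tilts up to ±25° the recovered EAR is within 0.03
of the geometric truth b/a; residual error comes from pixelization,
the denoising blur and rotation interpolation.

## Face-box tracking

A constant-velocity Kalman filter on the 8-dim state (four corner
coordinates plus per-frame velocities) bridges detection gaps:
detections that are absent or fall below a confidence threshold
(default 0.5) are replaced by the filter prediction. Defaults: process
noise 1e-2, measurement noise 1.0 (pixels²), loose velocity prior.
After 30 consecutive predicted frames the track is declared lost, the
box freezes, and the next usable detection re-initializes the filter.
The measurement update uses a pseudo-inverse so the zero-noise limit
(output pinned to the measurement) is exact. Corner ordering is
enforced by construction on output boxes.

## Temporal features

Windows are half-open `[start, end)`; a run truncated by a window edge
counts with its in-window duration, and a trailing partial window is
dropped. Features per window: longest eye-closed run × frame interval
`T0`; the number of mouth-open runs at least `min_yawn_seconds` long;
and frame-ratio PERCLOS (closed frames / total frames). The yawn
cut-off defaults to 4 s: typical yawns last about 6 s while speech and
laughter open the mouth only briefly, so 4 s separates the two with
margin; it is configurable. Invalid frames (no landmarks) inherit the
last valid state; a window more than half invalid is flagged unusable.
The P80 PERCLOS variant operates on a continuous closure signal in
[0, 1], locating the 20%/80% crossings of each blink cycle by linear
interpolation and averaging `(t3−t2)/(t4−t1)` over cycles; it exists
for completeness and is not used by the classifier.

## Classifier

A 3→m→1 feed-forward network with logistic activations in both layers,
binary cross-entropy loss, and Adam (lr 1e-3, β = 0.9/0.999) on seeded
minibatches of 8 for 4000 epochs; 90% of the data trains, 10%
validates, and per-epoch train/validation loss and accuracy are
recorded. The hidden activation is a documented choice (the standard
sizing literature motivates it but nothing in the pipeline depends on
it). Features are z-scored with training-split statistics because
their units are incommensurate (seconds, count, fraction); the scaling
travels with the model, making predictions invariant to consistent
affine re-encodings of the raw features. The decision cut-off is 0.5
with ties counted awake (conservative toward fewer false alarms).
Hidden-layer sizing uses the empirical rule `m = round(√(i+j)) + c`,
`c = 1..10` (for 3 inputs / 1 output: 3–12); a linear variant
`m = i + j + c` is available. `compare_hidden_nodes` reruns training
per candidate m at a fixed seed and tabulates the final losses and
accuracies; the default m = 4 balances fit quality against model size.
Training is implemented directly in numpy so that the exact regime
(batch schedule, optimizer state, history) is explicit and
reproducible bit-for-bit from a seed.

## Time-accumulation model

The cumulative fatigue value of a window with segment states
`x_i ∈ {0,1}` is

    a_F = (1/n) Σ_i [ x_i σ(x_i) − (1−x_i) σ(x_i) ]
        = (1/n) [ k σ(1) − (n−k) σ(0) ],

with σ the standard logistic and k the fatigue-segment count. Note the
logistic form: a printed variant with `1 − e^{−x}` in the denominator
is negative and unbounded near zero and cannot reproduce the model's
own level values; the standard logistic does, exactly. The levels for
k = 0..n form an arithmetic progression from −0.5 to σ(1) ≈ 0.7311
with gap (σ(1)+σ(0))/n. Candidate thresholds are the n midpoints of
adjacent levels (for n = 3: −0.295, 0.116, 0.526); `select_threshold`
scores each candidate's accuracy over a labeled collection and returns
the best (smallest on ties, favoring sensitivity). Decision rule:
fatigue iff `a_F ≥ θ_F`; with exact levels, equality at a midpoint
threshold is unreachable, so the convention only matters under
floating-point noise. With the j-th candidate threshold the decision
is provably the counting rule `k ≥ j+1` (midpoints interleave levels);
the suite checks this exhaustively for n ≤ 10. Under i.i.d.
segment-flip noise p on awake windows, the n = 3, θ = 0.116 rule
false-alarms with probability `3p²(1−p) + p³`, strictly below p for
p < 0.5 — the filtering property in closed form.

Defaults mirror the operating point used throughout: window 60 s (or
120 s), n = 3, θ_F = 0.116. Segment counts should stay well below
window/yawn-duration (≈ 10 for a 60 s window), or a yawn no longer
fits inside one segment; the runner warns when the segment length
drops below 1.5× the yawn cut-off. Window frame counts not divisible
by n give the first (count mod n) segments one extra frame.

## Synthetic data

The generator stands in for driving video, which cannot be shipped.
`generate_stream` simulates a session from a state schedule: awake
spans draw blinks (15/min, 0.1–0.4 s) from a Poisson process; fatigue
spans draw long closures (8/min, log-normal, median 2.5 s, σ_log 0.35)
and yawns (1/min, normal 6 ± 1 s); optional expression-noise events
(the "scenario 2" mode) depress the EAR below threshold for 3–6 s
during awake spans at a configurable rate (0.15/min in the tests,
matching sparse smiling/speaking episodes). Frame flags are realized
as per-frame EAR/MAR draws (open eyes 0.30 ± 0.015, closed
0.06 ± 0.01; mouth 0.15 ± 0.02 closed, 0.70 ± 0.05 open) and rendered
into a 68-point template face at 640×480 with Gaussian landmark jitter
(σ = 1 px), so the landmark pipeline genuinely recomputes the states
rather than receiving them. `generate_training_set` draws per-window
features from per-class distributions consistent with those stream
statistics, with exact class counts (default 500 windows, 70%
fatigue). `render_eye_image` draws antialiased ellipse eyes with
landmarks placed so the noiseless landmark EAR equals b/a exactly.

What the synthetic data does *not* emulate: real landmark-detector
error structure (correlated, pose-dependent), illumination effects,
head motion, partial occlusions, and individual physiological
variation. Passing tests therefore demonstrate that the algorithms are
implemented correctly and behave as designed under their stated
assumptions — not field accuracy on real drivers.

## Numerical and testing notes

Problem sizes in the suite are desk-scale by design: hour-long
simulated sessions at 30 fps (108k frames), 400-window training sets,
10k-window Monte Carlo runs, and exhaustive enumeration over all 2ⁿ
segment-state vectors for n ≤ 10. The classifier's quick fixtures
train for 400–600 epochs (the separable clusters converge long before
the full 4000-epoch regime, which the acceptance check still runs).
The expression-noise comparison trains the classifier on window
features extracted from a simulated 10 min awake + 10 min fatigue
session — the same path real deployments would use — and then requires
strictly fewer awake-window false alarms from the cumulative rule than
from the whole-window classifier on an identical noisy awake hour.

Known limitations: the tracker's constant-velocity model overshoots on
abrupt direction changes (bounded by the coast limit); the
image-processing EAR assumes the eye is the minority class of its crop
and a single connected bright/dark region; the accumulation model
resets per window and does not carry fatigue evidence across windows
(multi-hour continuous accumulation is out of scope); and calibration
of θ_F requires labeled windows of both classes.
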