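"""Synthetic fixtures: rendered eye images, landmark streams, and
labeled window datasets.

Real in-cab driving video is not shippable, so every input the pipeline
consumes is generated here with known ground truth:

* ``render_eye_image`` draws a bright ellipse eye (semi-axes a, b,
  optional tilt) on a dark background together with six idealized eye
  landmarks, so the image-processing EAR can be checked against the
  geometric truth b/a.
* ``generate_stream`` simulates a driving session as a 68-point
  landmark stream: awake spans contain short blinks, fatigue spans long
  eye closures and ~6 s yawns, and optional expression-noise events
  (smiling/speaking) depress the EAR below threshold for a few seconds
  during awake spans — the classic source of false fatigue alarms.
* ``generate_training_set`` draws per-window feature vectors from
  per-class distributions consistent with the stream statistics
  (defaults emulate a 500-window set with 350 fatigue / 150 awake).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmarks import (
    DEFAULT_EAR_THRESHOLD,
    DEFAULT_MAR_THRESHOLD,
    EyeLandmarks,
    LEFT_EYE,
    MOUTH,
    RIGHT_EYE,
)
from .temporal import FrameSeries

__all__ = [
    "ScenarioSpec",
    "SyntheticStream",
    "render_eye_image",
    "generate_stream",
    "generate_training_set",
]

AWAKE, FATIGUE = "awake", "fatigue"


@dataclass(frozen=True)
class ScenarioSpec:
    """Conditions for one simulated driving session.

    Rates are events per minute; durations in seconds.  Awake eye
    closures are blinks (~0.2 s); fatigue closures are log-normal with
    median ~2.5 s; yawns occur only in fatigue spans and last ~6 s;
    expression-noise events (rate > 0 = "scenario 2") depress the EAR
    below threshold for 3-6 s during awake spans.
    """

    duration_s: float = 3600.0
    fps: float = 30.0
    schedule: tuple = ((0.0, 3600.0, AWAKE),)
    window_seconds: float = 60.0
    blink_rate_awake: float = 15.0
    blink_duration_range: tuple = (0.1, 0.4)
    closure_rate_fatigue: float = 8.0
    closure_log_median_s: float = 2.5
    closure_log_sigma: float = 0.35
    yawn_rate_fatigue: float = 1.0
    yawn_duration_mean_s: float = 6.0
    yawn_duration_sd_s: float = 1.0
    noise_rate: float = 0.0
    noise_duration_range: tuple = (3.0, 6.0)
    landmark_jitter_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration must be positive")
        for r in (
            self.blink_rate_awake,
            self.closure_rate_fatigue,
            self.yawn_rate_fatigue,
            self.noise_rate,
        ):
            if r < 0:
                raise ValueError("rates must be non-negative")
        spans = sorted(self.schedule)
        if not spans or spans[0][0] != 0.0 or spans[-1][1] < self.duration_s:
            raise ValueError("schedule must cover [0, duration] without gaps")
        for (s0, e0, st0), (s1, e1, st1) in zip(spans, spans[1:]):
            if e0 != s1:
                raise ValueError("schedule must be contiguous (no gaps/overlap)")
            if st0 not in (AWAKE, FATIGUE) or st1 not in (AWAKE, FATIGUE):
                raise ValueError("schedule states must be 'awake' or 'fatigue'")
        if self.schedule[0][2] not in (AWAKE, FATIGUE):
            raise ValueError("schedule states must be 'awake' or 'fatigue'")


def render_eye_image(
    a: float,
    b: float,
    tilt_deg: float = 0.0,
    image_size: tuple[int, int] = (160, 240),
    noise_level: float = 0.0,
    seed: int = 0,
    background: float = 20.0,
    foreground: float = 230.0,
) -> tuple[np.ndarray, EyeLandmarks, float]:
    """Render a bright-on-dark ellipse eye with known geometry.

    The ellipse has horizontal semi-axis ``a`` and vertical ``b``
    (pixels) and is rotated by ``tilt_deg`` in image coordinates
    (positive = eye axis sloping downward to the right).  Landmarks:
    P1/P4 at the ellipse x-extremes, the lid points P2/P3/P5/P6 at
    (+-a/2, -+b) so the landmark EAR of the noiseless hexagon equals
    the geometric truth b/a.  Edges are antialiased by 3x3
    supersampling; ``noise_level`` adds Gaussian pixel noise.

    Returns (image, landmarks, true_ear) with true_ear = b / a.
    """
    if a <= 0:
        raise ValueError("horizontal semi-axis a must be positive")
    if b < 0 or b > a:
        raise ValueError("need 0 <= b <= a")
    rows, cols = image_size
    cy, cx = rows / 2.0, cols / 2.0
    phi = np.radians(tilt_deg)
    cphi, sphi = np.cos(phi), np.sin(phi)

    ss = 3  # supersampling factor
    y = (np.arange(rows * ss) + 0.5) / ss - 0.5 - cy
    x = (np.arange(cols * ss) + 0.5) / ss - 0.5 - cx
    dx, dy = np.meshgrid(x, y)
    u = dx * cphi + dy * sphi
    v = -dx * sphi + dy * cphi
    if b == 0:
        inside = np.zeros_like(u, dtype=bool)
    else:
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    coverage = inside.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    img = background + (foreground - background) * coverage
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_level, size=img.shape)
    img = np.clip(img, 0.0, 255.0)

    def _place(u0, v0):
        return np.array(
            [cx + u0 * cphi - v0 * sphi, cy + u0 * sphi + v0 * cphi]
        )

    eye = EyeLandmarks(
        p1=_place(-a, 0.0),
        p2=_place(-a / 2.0, -b),
        p3=_place(a / 2.0, -b),
        p4=_place(a, 0.0),
        p5=_place(a / 2.0, b),
        p6=_place(-a / 2.0, b),
    )
    return img, eye, b / a


# --- landmark-template face (640 x 480 frame) -------------------------------

_FRAME_W, _FRAME_H = 640, 480
_EYE_HALF_W = 30.0
_EYE_LID_X = 15.0
_MOUTH_HALF_W = 40.0
_MOUTH_LIP_X = 13.0
_RIGHT_EYE_C = (260.0, 220.0)
_LEFT_EYE_C = (380.0, 220.0)
_MOUTH_C = (320.0, 330.0)


def _template_points() -> np.ndarray:
    """A static, roughly face-shaped 68-point template; only the eye and
    mouth indices are animated."""
    pts = np.zeros((68, 2))
    # jaw 0-16: lower half-ellipse
    t = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17, 0] = 320 + 140 * np.cos(t)
    pts[0:17, 1] = 240 - 170 * np.sin(t)
    # brows 17-26
    pts[17:22, 0] = np.linspace(215, 295, 5)
    pts[17:22, 1] = 185.0
    pts[22:27, 0] = np.linspace(345, 425, 5)
    pts[22:27, 1] = 185.0
    # nose 27-35
    pts[27:31, 0] = 320.0
    pts[27:31, 1] = np.linspace(215, 275, 4)
    pts[31:36, 0] = np.linspace(300, 340, 5)
    pts[31:36, 1] = 285.0
    return pts


def _animate_frames(
    ear: np.ndarray, mar: np.ndarray, jitter: np.ndarray
) -> np.ndarray:
    """Build (n, 68, 2) landmark frames realizing per-frame EAR/MAR.

    Lid points sit at (+-half_w/2, -+half_w*ear) around each eye
    centre, so the landmark EAR of the jitter-free frame equals ``ear``
    exactly; same construction for the mouth.
    """
    n = len(ear)
    pts = np.broadcast_to(_template_points(), (n, 68, 2)).copy()

    for (ecx, ecy), idx in ((_RIGHT_EYE_C, RIGHT_EYE), (_LEFT_EYE_C, LEFT_EYE)):
        i1, i2, i3, i4, i5, i6 = idx
        half_gap = _EYE_HALF_W * ear  # vertical half-distance of lids
        pts[:, i1] = (ecx - _EYE_HALF_W, ecy)
        pts[:, i4] = (ecx + _EYE_HALF_W, ecy)
        for i_up, i_dn, lx in ((i2, i6, -_EYE_LID_X), (i3, i5, _EYE_LID_X)):
            pts[:, i_up, 0] = ecx + lx
            pts[:, i_up, 1] = ecy - half_gap
            pts[:, i_dn, 0] = ecx + lx
            pts[:, i_dn, 1] = ecy + half_gap

    mcx, mcy = _MOUTH_C
    i1, i2, i3, i4, i5, i6 = MOUTH
    half_gap = _MOUTH_HALF_W * mar
    pts[:, i1] = (mcx - _MOUTH_HALF_W, mcy)
    pts[:, i4] = (mcx + _MOUTH_HALF_W, mcy)
    for i_up, i_dn, lx in ((i2, i6, -_MOUTH_LIP_X), (i3, i5, _MOUTH_LIP_X)):
        pts[:, i_up, 0] = mcx + lx
        pts[:, i_up, 1] = mcy - half_gap
        pts[:, i_dn, 0] = mcx + lx
        pts[:, i_dn, 1] = mcy + half_gap
    # inner lips 60-67 track the outer mouth loosely (static otherwise)
    pts[:, 60:68, 0] = np.linspace(mcx - 25, mcx + 25, 8)
    pts[:, 60:68, 1] = mcy

    return pts + jitter


@dataclass
class SyntheticStream:
    """One simulated session: landmark stream, frame truth, window labels."""

    spec: ScenarioSpec
    landmarks: pd.DataFrame  # frame_index, timestamp, x0..y67, valid
    truth: pd.DataFrame  # frame_index, timestamp, eye_closed, mouth_open, state
    window_labels: pd.DataFrame  # window_id, start_s, end_s, label
    observations: FrameSeries  # truth-derived frame series

    @property
    def points(self) -> np.ndarray:
        cols = [f"{ax}{i}" for i in range(68) for ax in ("x", "y")]
        return self.landmarks[cols].to_numpy(dtype=float).reshape(-1, 68, 2)


def _poisson_events(rng, span_start, span_end, rate_per_min, dur_sampler):
    """Homogeneous Poisson events inside a span; durations clipped to it."""
    span = span_end - span_start
    n = rng.poisson(rate_per_min * span / 60.0)
    events = []
    for t in np.sort(rng.uniform(span_start, span_end, size=n)):
        d = float(dur_sampler())
        events.append((t, min(t + d, span_end)))
    return events


def generate_stream(spec: ScenarioSpec) -> SyntheticStream:
    """Simulate a session per the scenario spec; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.fps))
    t0 = 1.0 / spec.fps
    t = np.arange(n_frames) * t0

    eye_closed = np.zeros(n_frames, dtype=bool)
    mouth_open = np.zeros(n_frames, dtype=bool)
    state = np.empty(n_frames, dtype=object)

    def mark(flags, start, end):
        i0 = int(np.ceil(start / t0 - 1e-9))
        i1 = int(np.ceil(end / t0 - 1e-9))
        flags[max(i0, 0) : min(i1, n_frames)] = True

    for span_start, span_end, span_state in sorted(spec.schedule):
        span_end = min(span_end, spec.duration_s)
        i0 = int(np.ceil(span_start / t0 - 1e-9))
        i1 = int(np.ceil(span_end / t0 - 1e-9))
        state[i0:i1] = span_state

        if span_state == AWAKE:
            lo, hi = spec.blink_duration_range
            for s, e in _poisson_events(
                rng, span_start, span_end, spec.blink_rate_awake,
                lambda: rng.uniform(lo, hi),
            ):
                mark(eye_closed, s, e)
            if spec.noise_rate > 0:
                nlo, nhi = spec.noise_duration_range
                for s, e in _poisson_events(
                    rng, span_start, span_end, spec.noise_rate,
                    lambda: rng.uniform(nlo, nhi),
                ):
                    mark(eye_closed, s, e)  # expression noise mimics closure
        else:
            mu = np.log(spec.closure_log_median_s)
            for s, e in _poisson_events(
                rng, span_start, span_end, spec.closure_rate_fatigue,
                lambda: rng.lognormal(mu, spec.closure_log_sigma),
            ):
                mark(eye_closed, s, e)
            for s, e in _poisson_events(
                rng, span_start, span_end, spec.yawn_rate_fatigue,
                lambda: max(
                    rng.normal(spec.yawn_duration_mean_s, spec.yawn_duration_sd_s),
                    1.0,
                ),
            ):
                mark(mouth_open, s, e)

    # realized per-frame openness ratios
    ear_open = rng.normal(0.30, 0.015, size=n_frames)
    ear_closed = np.clip(rng.normal(0.06, 0.01, size=n_frames), 0.01, None)
    ear = np.where(eye_closed, ear_closed, ear_open)
    mar_closed = np.clip(rng.normal(0.15, 0.02, size=n_frames), 0.02, None)
    mar_open = rng.normal(0.70, 0.05, size=n_frames)
    mar = np.where(mouth_open, mar_open, mar_closed)

    jitter = rng.normal(0.0, spec.landmark_jitter_px, size=(n_frames, 68, 2))
    pts = _animate_frames(ear, mar, jitter)

    cols = {"frame_index": np.arange(n_frames), "timestamp": t}
    flat = pts.reshape(n_frames, 136)
    for i in range(68):
        cols[f"x{i}"] = flat[:, 2 * i]
        cols[f"y{i}"] = flat[:, 2 * i + 1]
    cols["valid"] = np.ones(n_frames, dtype=bool)
    landmarks = pd.DataFrame(cols)

    truth = pd.DataFrame(
        {
            "frame_index": np.arange(n_frames),
            "timestamp": t,
            "eye_closed": eye_closed,
            "mouth_open": mouth_open,
            "state": state,
        }
    )

    frames_per_window = int(round(spec.window_seconds * spec.fps))
    n_windows = n_frames // frames_per_window
    rows = []
    for w in range(n_windows):
        sl = state[w * frames_per_window : (w + 1) * frames_per_window]
        frac_fatigue = np.mean(sl == FATIGUE)
        rows.append(
            {
                "window_id": w,
                "start_s": w * spec.window_seconds,
                "end_s": (w + 1) * spec.window_seconds,
                "label": int(frac_fatigue > 0.5),
            }
        )
    window_labels = pd.DataFrame(rows)

    observations = FrameSeries(
        eye_closed=eye_closed,
        mouth_open=mouth_open,
        t0=t0,
        frame_index=np.arange(n_frames),
        timestamp=t,
        ear=ear,
        mar=mar,
    )
    return SyntheticStream(
        spec=spec,
        landmarks=landmarks,
        truth=truth,
        window_labels=window_labels,
        observations=observations,
    )


def generate_training_set(
    n_windows: int = 500,
    fatigue_fraction: float = 0.7,
    seed: int = 0,
    window_seconds: float = 60.0,
) -> pd.DataFrame:
    """Labeled per-window feature table for classifier training.

    Per-class feature distributions match what ``generate_stream``
    produces for pure awake / fatigue spans: awake windows have blink
    closures well under 1 s, no yawns and PERCLOS of a few percent;
    fatigue windows have multi-second closures, mostly >= 1 yawn and
    PERCLOS of roughly 0.2-0.5.  Class counts are exact (e.g. n=500,
    fraction 0.7 -> 350 fatigue + 150 awake).
    """
    if n_windows < 10:
        raise ValueError("need at least 10 windows")
    if not 0.0 < fatigue_fraction < 1.0:
        raise ValueError("fatigue_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_fat = int(round(n_windows * fatigue_fraction))
    n_awk = n_windows - n_fat

    awake = pd.DataFrame(
        {
            "longest_closure_s": np.clip(
                rng.lognormal(np.log(0.25), 0.3, size=n_awk), 0.05, 0.9
            ),
            "yawn_count": np.zeros(n_awk, dtype=int),
            "perclos": rng.beta(2.0, 40.0, size=n_awk),
            "label": np.zeros(n_awk, dtype=int),
        }
    )
    fatigue = pd.DataFrame(
        {
            "longest_closure_s": np.clip(
                2.6 + rng.lognormal(np.log(1.2), 0.5, size=n_fat),
                None,
                window_seconds,
            ),
            "yawn_count": 1 + rng.poisson(0.8, size=n_fat),
            "perclos": 0.32 + 0.23 * rng.beta(2.0, 3.0, size=n_fat),
            "label": np.ones(n_fat, dtype=int),
        }
    )
    table = pd.concat([awake, fatigue], ignore_index=True)
    return table.sample(frac=1.0, random_state=seed).reset_index(drop=True)
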