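"""Time-cumulative fatigue model: segment-wise evidence accumulation.

Fatigue builds up over time, while expression noise (smiling, speaking)
produces short, isolated false "fatigue" classifications.  Both facts
motivate judging a detection window from its sub-segments rather than
as a whole: the window is split into n > 1 equal segments, each segment
is classified awake (0) or fatigue (1), and the binary states x_i are
pooled into a cumulative fatigue value

    a_F = (1/n) * sum_i [ x_i * sigma(x_i) - (1 - x_i) * sigma(x_i) ]

with sigma the standard logistic.  Each fatigue segment contributes
+sigma(1)/n and each awake segment -sigma(0)/n, so a_F depends on the
states only through the fatigue count k and takes one of n + 1 evenly
spaced levels

    a_F^k = (1/n) * [ k * sigma(1) - (n - k) * sigma(0) ],  k = 0..n,

ranging from -0.5 (all awake) to sigma(1) ~ 0.731 (all fatigue).  The
candidate decision thresholds are the midpoints of adjacent levels; the
operating threshold is calibrated by sweeping the candidates over a
labeled collection and keeping the most accurate one.  A window is
declared fatigued when a_F >= theta_F, which is equivalent to the
counting rule "at least j+1 fatigue segments" for the j-th candidate —
a single noisy fatigue segment in an awake window is filtered out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import MLPModel, predict
from .temporal import (
    DEFAULT_MIN_YAWN_SECONDS,
    FrameSeries,
    iter_windows,
    split_segments,
    window_features,
)

__all__ = [
    "SegmentDecisions",
    "CumulativeResult",
    "WindowDecision",
    "logistic",
    "fatigue_accumulation",
    "cumulative_levels",
    "candidate_thresholds",
    "select_threshold",
    "decide_window",
    "run_segmented_detection",
    "overall_accuracy",
    "DEFAULT_THETA",
    "DEFAULT_SEGMENTS",
]

DEFAULT_SEGMENTS = 3
DEFAULT_THETA = 0.116  # calibrated midpoint threshold for n = 3


def logistic(x):
    """Standard logistic sigma(x) = 1 / (1 + exp(-x))."""
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    e = np.exp(arr[~pos])
    out[~pos] = e / (1.0 + e)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SegmentDecisions:
    """The n per-segment binary states of one window (1 = fatigue)."""

    x: tuple

    def __post_init__(self) -> None:
        x = tuple(int(v) for v in self.x)
        if any(v not in (0, 1) for v in x):
            raise ValueError("segment states must be 0 or 1")
        if len(x) <= 1:
            raise ValueError("need n > 1 segments")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def k(self) -> int:
        return sum(self.x)


@dataclass(frozen=True)
class CumulativeResult:
    """Accumulated fatigue value, threshold, and the window decision."""

    a_f: float
    theta: float
    fatigue: bool

    @property
    def state(self) -> str:
        return "fatigue" if self.fatigue else "awake"


def fatigue_accumulation(seg: SegmentDecisions) -> float:
    """Cumulative fatigue value a_F of one window's segment states.

    Permutation-invariant (depends on x only through k) and strictly
    increasing in k, bounded in [-sigma(0), sigma(1)] = [-0.5, 0.731].
    """
    n, k = seg.n, seg.k
    return float((k * logistic(1.0) - (n - k) * logistic(0.0)) / n)


def cumulative_levels(n: int) -> np.ndarray:
    """The n + 1 attainable a_F values for k = 0..n fatigue segments.

    An arithmetic progression from -0.5 to sigma(1) with gap
    (sigma(1) + sigma(0)) / n; for n = 3:
    (-0.5, -0.0896, 0.3207, 0.7311).
    """
    if n <= 1:
        raise ValueError("need n > 1 segments")
    k = np.arange(n + 1, dtype=float)
    return (k * logistic(1.0) - (n - k) * logistic(0.0)) / n


def candidate_thresholds(n: int) -> np.ndarray:
    """Midpoints of adjacent cumulative levels: the n candidate
    operating thresholds (for n = 3: -0.295, 0.116, 0.526)."""
    levels = cumulative_levels(n)
    return 0.5 * (levels[:-1] + levels[1:])


def decide_window(seg: SegmentDecisions, theta: float) -> CumulativeResult:
    """Window decision: fatigue iff a_F >= theta.

    Midpoint thresholds make equality unreachable for exact levels, so
    the >= convention only matters under floating-point noise.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    a_f = fatigue_accumulation(seg)
    return CumulativeResult(a_f=a_f, theta=float(theta), fatigue=bool(a_f >= theta))


def select_threshold(
    windows,
    labels,
    n: int,
) -> tuple[float, pd.DataFrame]:
    """Calibrate theta_F over a labeled collection of segment decisions.

    ``windows`` is a sequence of SegmentDecisions (all with the given
    n), ``labels`` the true window states (1 = fatigue).  Every
    candidate threshold classifies every window (fatigue iff
    a_F >= theta); the candidate with the highest accuracy wins,
    smallest on ties.  Returns (theta, accuracy table) with columns
    threshold, correct, total, accuracy.
    """
    windows = list(windows)
    labels = np.asarray(labels, dtype=int)
    if len(windows) == 0:
        raise ValueError("empty window collection")
    if len(windows) != len(labels):
        raise ValueError("windows and labels must align")
    if np.unique(labels).size < 2:
        raise ValueError("calibration needs both awake and fatigue windows")
    if any(w.n != n for w in windows):
        raise ValueError(f"all windows must have n = {n} segments")

    a_f = np.array([fatigue_accumulation(w) for w in windows])
    rows = []
    for theta in candidate_thresholds(n):
        pred = (a_f >= theta).astype(int)
        correct = int(np.sum(pred == labels))
        rows.append(
            {
                "threshold": float(theta),
                "correct": correct,
                "total": len(labels),
                "accuracy": correct / len(labels),
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["accuracy"].idxmax(), "threshold"]  # first max
    return float(best), table


@dataclass(frozen=True)
class WindowDecision:
    """One window's segmented-detection outcome (a Fig.-8-style trace
    row): segment states, k, a_F, theta, and the binary decision."""

    window_id: int
    start_s: float
    end_s: float
    segment_states: tuple
    a_f: float
    theta: float
    fatigue: bool

    @property
    def k(self) -> int:
        return sum(self.segment_states)

    @property
    def state(self) -> str:
        return "fatigue" if self.fatigue else "awake"


def run_segmented_detection(
    series: FrameSeries,
    window_seconds: float,
    n: int,
    model: MLPModel,
    theta: float = DEFAULT_THETA,
    min_yawn_seconds: float = DEFAULT_MIN_YAWN_SECONDS,
) -> list[WindowDecision]:
    """Segment-wise detection over a frame stream.

    Each half-open window of ``window_seconds`` is split into n equal
    contiguous segments; the three temporal features of every segment
    feed the classifier, and the n binary states are pooled by the
    accumulation rule into the window decision.
    """
    if n <= 1:
        raise ValueError("need n > 1 segments")
    frames_per_window = int(round(window_seconds / series.t0))
    if frames_per_window < n:
        raise ValueError("segment shorter than one frame")
    if window_seconds / n < 1.5 * min_yawn_seconds:
        warnings.warn(
            f"segments of {window_seconds / n:.1f} s leave little margin over "
            f"the {min_yawn_seconds:.1f} s yawn cut-off; yawns may be missed",
            stacklevel=2,
        )

    decisions = []
    for window_id, start, window in iter_windows(series, window_seconds):
        states = []
        for segment in split_segments(window, n):
            feats = window_features(segment, min_yawn_seconds)
            _, state = predict(model, feats)
            states.append(int(state[0]))
        seg = SegmentDecisions(tuple(states))
        result = decide_window(seg, theta)
        decisions.append(
            WindowDecision(
                window_id=window_id,
                start_s=start * series.t0,
                end_s=(start + frames_per_window) * series.t0,
                segment_states=tuple(states),
                a_f=result.a_f,
                theta=result.theta,
                fatigue=result.fatigue,
            )
        )
    return decisions


def overall_accuracy(correct_counts, totals) -> float:
    """Pooled accuracy from per-class (correct, total) counts, e.g.
    45 awake / 40 correct plus 15 fatigue / 14 correct -> 0.90."""
    correct = np.asarray(correct_counts, dtype=float)
    total = np.asarray(totals, dtype=float)
    if np.any(correct > total) or np.any(total <= 0):
        raise ValueError("invalid counts")
    return float(correct.sum() / total.sum())
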