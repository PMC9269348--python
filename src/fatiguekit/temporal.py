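"""Windowed temporal fatigue features from per-frame observations.

Three indicators summarize a detection window:

* ``longest_closure`` F_t — the longest run of consecutive eye-closed
  frames times the frame interval T0 (seconds),
* ``count_yawns`` — the number of mouth-open runs lasting at least a
  yawn-duration cut-off (yawns last ~6 s; brief opens from speech or
  laughter are excluded by the cut-off),
* ``perclos_frames`` F_p — the fraction of frames with the eyes closed
  (the frame-ratio PERCLOS used by the classifier).

A continuous-signal P80 PERCLOS (time between the 80%-closure crossings
over the time between the 20%-closure crossings of each blink cycle) is
provided for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrameSeries",
    "WindowFeatures",
    "longest_closure",
    "count_yawns",
    "perclos_frames",
    "perclos_p80",
    "window_features",
    "iter_windows",
    "split_segments",
]

DEFAULT_MIN_YAWN_SECONDS = 4.0


@dataclass
class FrameSeries:
    """An ordered run of frame observations at a fixed frame interval.

    Invalid frames (landmark detection failed) inherit the previous
    valid eye/mouth state; a window with more than half invalid frames
    is flagged unusable downstream.
    """

    eye_closed: np.ndarray
    mouth_open: np.ndarray
    t0: float
    frame_index: np.ndarray | None = None
    timestamp: np.ndarray | None = None
    ear: np.ndarray | None = None
    mar: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eye_closed = np.asarray(self.eye_closed, dtype=bool)
        self.mouth_open = np.asarray(self.mouth_open, dtype=bool)
        if self.t0 <= 0:
            raise ValueError("frame interval t0 must be positive")
        n = len(self.eye_closed)
        if len(self.mouth_open) != n:
            raise ValueError("eye and mouth state arrays must align")
        if self.frame_index is None:
            self.frame_index = np.arange(n)
        else:
            self.frame_index = np.asarray(self.frame_index)
            if np.any(np.diff(self.frame_index) <= 0):
                raise ValueError("frame indices must be strictly increasing")
        if self.timestamp is None:
            self.timestamp = self.frame_index * self.t0
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        self._fill_invalid()

    def _fill_invalid(self) -> None:
        """Carry the last valid eye/mouth state through invalid frames.

        Leading invalid frames default to open eyes / closed mouth."""
        if self.valid.all():
            return
        eye = self.eye_closed.copy()
        mouth = self.mouth_open.copy()
        last_eye, last_mouth = False, False
        for i in range(len(eye)):
            if self.valid[i]:
                last_eye, last_mouth = eye[i], mouth[i]
            else:
                eye[i], mouth[i] = last_eye, last_mouth
        self.eye_closed = eye
        self.mouth_open = mouth

    def __len__(self) -> int:
        return len(self.eye_closed)

    @property
    def duration(self) -> float:
        return len(self) * self.t0

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - np.mean(self.valid)) if len(self) else 0.0

    @property
    def usable(self) -> bool:
        return self.invalid_fraction <= 0.5

    def slice(self, start: int, stop: int) -> "FrameSeries":
        sl = slice(start, stop)
        return FrameSeries(
            eye_closed=self.eye_closed[sl],
            mouth_open=self.mouth_open[sl],
            t0=self.t0,
            frame_index=self.frame_index[sl],
            timestamp=self.timestamp[sl],
            ear=None if self.ear is None else self.ear[sl],
            mar=None if self.mar is None else self.mar[sl],
            valid=self.valid[sl],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, t0: float) -> "FrameSeries":
        return cls(
            eye_closed=df["eye_closed"].to_numpy(dtype=bool),
            mouth_open=df["mouth_open"].to_numpy(dtype=bool),
            t0=t0,
            frame_index=df["frame_index"].to_numpy(),
            timestamp=df["timestamp"].to_numpy(dtype=float)
            if "timestamp" in df
            else None,
            ear=df["ear"].to_numpy(dtype=float) if "ear" in df else None,
            mar=df["mar"].to_numpy(dtype=float) if "mar" in df else None,
            valid=df["valid"].to_numpy(dtype=bool) if "valid" in df else None,
        )


@dataclass(frozen=True)
class WindowFeatures:
    """The classifier's 3-vector for one window."""

    longest_closure_s: float
    yawn_count: int
    perclos: float
    window_id: int = 0
    usable: bool = True

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.longest_closure_s, self.yawn_count, self.perclos], dtype=float
        )


def _run_lengths(flags: np.ndarray) -> np.ndarray:
    """Lengths of maximal True runs, in order."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return np.array([], dtype=int)
    padded = np.concatenate([[False], flags, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def longest_closure(series: FrameSeries) -> float:
    """Longest continuous eye closure in seconds: max run length x T0."""
    if len(series) == 0:
        raise ValueError("empty series")
    runs = _run_lengths(series.eye_closed)
    return float(runs.max() * series.t0) if runs.size else 0.0


def count_yawns(
    series: FrameSeries, min_yawn_seconds: float = DEFAULT_MIN_YAWN_SECONDS
) -> int:
    """Number of mouth-open runs lasting at least ``min_yawn_seconds``."""
    if min_yawn_seconds <= 0:
        raise ValueError("min_yawn_seconds must be positive")
    runs = _run_lengths(series.mouth_open)
    return int(np.sum(runs * series.t0 >= min_yawn_seconds))


def perclos_frames(series: FrameSeries) -> float:
    """Frame-ratio PERCLOS: closed frames / total frames."""
    if len(series) == 0:
        raise ValueError("empty series")
    return float(np.mean(series.eye_closed))


def _crossings(t, y, level, rising: bool):
    """Times where y crosses ``level`` (linear interpolation)."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    out = []
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if rising and y0 < level <= y1:
            out.append(t[i] + (level - y0) / (y1 - y0) * (t[i + 1] - t[i]))
        elif not rising and y0 >= level > y1:
            out.append(t[i] + (level - y0) / (y1 - y0) * (t[i + 1] - t[i]))
    return out


def perclos_p80(closure: np.ndarray, timestamps: np.ndarray) -> float:
    """P80 PERCLOS on a continuous eye-closure signal in [0, 1].

    Each blink cycle contributes (t3 - t2) / (t4 - t1) where t1/t2 are
    the rising 20%/80% closure crossings and t3/t4 the falling 80%/20%
    ones; cycles are averaged.  Raises if no complete cycle exists.
    """
    closure = np.asarray(closure, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if closure.shape != timestamps.shape or closure.ndim != 1:
        raise ValueError("closure and timestamps must be equal-length 1-D")
    up20 = _crossings(timestamps, closure, 0.2, rising=True)
    up80 = _crossings(timestamps, closure, 0.8, rising=True)
    dn80 = _crossings(timestamps, closure, 0.8, rising=False)
    dn20 = _crossings(timestamps, closure, 0.2, rising=False)

    ratios = []
    for t2 in up80:
        t1c = [t for t in up20 if t < t2]
        t3c = [t for t in dn80 if t > t2]
        if not t1c or not t3c:
            continue
        t1, t3 = t1c[-1], t3c[0]
        t4c = [t for t in dn20 if t > t3]
        if not t4c:
            continue
        t4 = t4c[0]
        ratios.append((t3 - t2) / (t4 - t1))
    if not ratios:
        raise ValueError(
            "no complete close-open cycle crossing 80%/20% closure found"
        )
    return float(np.mean(ratios))


def window_features(
    series: FrameSeries,
    min_yawn_seconds: float = DEFAULT_MIN_YAWN_SECONDS,
    window_id: int = 0,
) -> WindowFeatures:
    """Assemble (F_t, yawn count, F_p) for one window."""
    return WindowFeatures(
        longest_closure_s=longest_closure(series),
        yawn_count=count_yawns(series, min_yawn_seconds),
        perclos=perclos_frames(series),
        window_id=window_id,
        usable=series.usable,
    )


def iter_windows(series: FrameSeries, window_seconds: float):
    """Yield (window_id, start_frame, sub-series) over half-open
    [start, end) windows; a trailing partial window is dropped."""
    frames_per_window = int(round(window_seconds / series.t0))
    if frames_per_window < 1:
        raise ValueError("window shorter than one frame")
    n_windows = len(series) // frames_per_window
    for w in range(n_windows):
        start = w * frames_per_window
        yield w, start, series.slice(start, start + frames_per_window)


def split_segments(series: FrameSeries, n: int) -> list[FrameSeries]:
    """Split a window into n contiguous segments; when the frame count is
    not divisible by n, the first (count mod n) segments get one extra
    frame."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total = len(series)
    if total < n:
        raise ValueError(f"cannot split {total} frames into {n} segments")
    base, extra = divmod(total, n)
    out = []
    start = 0
    for i in range(n):
        size = base + (1 if i < extra else 0)
        out.append(series.slice(start, start + size))
        start += size
    return out
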