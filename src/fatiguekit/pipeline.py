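"""End-to-end detection pipelines.

Two variants share the front end (landmarks -> per-frame EAR/MAR ->
binary eye/mouth states -> windows):

* BP pipeline: the three temporal features of each *whole* window feed
  the classifier directly — one probability and binary state per
  window.
* Cumulative pipeline: each window is split into n segments, each
  segment classified, and the segment states pooled by the
  time-accumulation rule (fatigue iff a_F >= theta).  Isolated noisy
  fatigue segments — e.g. smiling/speaking episodes that depress the
  EAR — are filtered out instead of flagging the whole window.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .accumulation import WindowDecision, run_segmented_detection
from .classifier import MLPModel, predict
from .io import PipelineConfig, landmarks_to_points
from .landmarks import compute_observations
from .temporal import FrameSeries, iter_windows, window_features

__all__ = [
    "BPWindowDecision",
    "series_from_landmarks",
    "extract_window_features",
    "run_bp_pipeline",
    "run_cumulative_pipeline",
    "decisions_to_frame",
]


@dataclass(frozen=True)
class BPWindowDecision:
    """One window's whole-window classifier outcome."""

    window_id: int
    start_s: float
    end_s: float
    probability: float
    fatigue: bool

    @property
    def state(self) -> str:
        return "fatigue" if self.fatigue else "awake"


def series_from_landmarks(
    landmarks: pd.DataFrame, config: PipelineConfig
) -> FrameSeries:
    """Landmark stream -> per-frame observation series."""
    if len(landmarks) == 0:
        raise ValueError("empty landmark stream")
    pts = landmarks_to_points(landmarks)
    obs = compute_observations(
        pts,
        timestamps=landmarks["timestamp"].to_numpy(dtype=float),
        valid=landmarks["valid"].to_numpy(dtype=bool),
        ear_threshold=config.ear_threshold,
        mar_threshold=config.mar_threshold,
    )
    return FrameSeries.from_dataframe(obs, t0=config.t0)


def extract_window_features(
    series: FrameSeries, config: PipelineConfig
) -> pd.DataFrame:
    """Whole-window feature table in the features CSV schema."""
    rows = []
    for window_id, start, window in iter_windows(series, config.window_seconds):
        f = window_features(window, config.min_yawn_seconds, window_id=window_id)
        rows.append(
            {
                "window_id": window_id,
                "start_s": start * series.t0,
                "longest_closure_s": f.longest_closure_s,
                "yawn_count": f.yawn_count,
                "perclos": f.perclos,
            }
        )
    return pd.DataFrame(rows)


def run_bp_pipeline(
    config: PipelineConfig,
    landmarks: pd.DataFrame,
    model: MLPModel,
) -> list[BPWindowDecision]:
    """Whole-window detection: landmarks -> features -> classifier."""
    series = series_from_landmarks(landmarks, config)
    decisions = []
    for window_id, start, window in iter_windows(series, config.window_seconds):
        feats = window_features(window, config.min_yawn_seconds)
        proba, state = predict(model, feats)
        decisions.append(
            BPWindowDecision(
                window_id=window_id,
                start_s=start * series.t0,
                end_s=start * series.t0 + config.window_seconds,
                probability=float(proba[0]),
                fatigue=bool(state[0]),
            )
        )
    return decisions


def run_cumulative_pipeline(
    config: PipelineConfig,
    landmarks: pd.DataFrame,
    model: MLPModel,
) -> list[WindowDecision]:
    """Segmented detection with time accumulation (n segments, theta)."""
    series = series_from_landmarks(landmarks, config)
    return run_segmented_detection(
        series,
        window_seconds=config.window_seconds,
        n=config.segments,
        model=model,
        theta=config.theta,
        min_yawn_seconds=config.min_yawn_seconds,
    )


def decisions_to_frame(decisions) -> pd.DataFrame:
    """Decision list -> tidy DataFrame (works for both pipeline kinds)."""
    rows = []
    for d in decisions:
        row = {
            "window_id": d.window_id,
            "start_s": d.start_s,
            "end_s": d.end_s,
            "state": int(d.fatigue),
        }
        if hasattr(d, "a_f"):
            row.update(k=d.k, a_f=d.a_f, theta=d.theta)
        if hasattr(d, "probability"):
            row.update(probability=d.probability)
        rows.append(row)
    return pd.DataFrame(rows)
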