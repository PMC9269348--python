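"""Tabular schemas, readers/writers, configuration and run manifests.

All pipeline artifacts are plain CSV/JSON:

* landmark stream: ``frame_index, timestamp, x0, y0, ..., x67, y67, valid``
* observations: ``frame_index, timestamp, ear, mar, eye_closed,
  mouth_open, valid``
* detections: ``frame, x1, y1, x2, y2, confidence`` (empty fields =
  absent detection); tracked output adds a ``source`` column
* window features: ``window_id, start_s, longest_closure_s, yawn_count,
  perclos[, label]``
* window decisions: ``window_id, start_s, end_s, k, a_f, theta, state``

Readers validate the header and the monotonicity of frame indices and
raise :class:`SchemaError` naming the offending column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .tracking import FaceBox

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "LANDMARK_COLUMNS",
    "read_landmarks",
    "write_landmarks",
    "read_observations",
    "write_observations",
    "read_features",
    "write_features",
    "read_detections",
    "write_tracked",
    "write_decisions",
    "write_manifest",
]

LANDMARK_COLUMNS = (
    ["frame_index", "timestamp"]
    + [f"{ax}{i}" for i in range(68) for ax in ("x", "y")]
    + ["valid"]
)
OBSERVATION_COLUMNS = [
    "frame_index", "timestamp", "ear", "mar", "eye_closed", "mouth_open", "valid",
]
FEATURE_COLUMNS_IO = [
    "window_id", "start_s", "longest_closure_s", "yawn_count", "perclos",
]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with the calibrated defaults."""

    ear_threshold: float = 0.21
    mar_threshold: float = 0.4
    min_yawn_seconds: float = 4.0
    window_seconds: float = 60.0
    segments: int = 3
    theta: float = 0.116
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ear_threshold, self.mar_threshold, self.min_yawn_seconds) <= 0:
            raise ValueError("thresholds must be positive")
        if self.segments <= 1:
            raise ValueError("need more than one segment (n > 1)")
        if self.fps <= 0 or self.window_seconds <= 0:
            raise ValueError("fps and window_seconds must be positive")
        if self.window_seconds * self.fps / self.segments < 1.0:
            raise ValueError("segments must span at least one frame")

    @property
    def t0(self) -> float:
        return 1.0 / self.fps


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_monotone(df: pd.DataFrame, col: str, path) -> None:
    v = df[col].to_numpy()
    if len(v) and np.any(np.diff(v) <= 0):
        bad = int(np.flatnonzero(np.diff(v) <= 0)[0]) + 1
        raise SchemaError(f"{path}: {col} not strictly increasing at row {bad}")


def read_landmarks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, LANDMARK_COLUMNS, path)
    _check_monotone(df, "frame_index", path)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_landmarks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def landmarks_to_points(df: pd.DataFrame) -> np.ndarray:
    cols = [f"{ax}{i}" for i in range(68) for ax in ("x", "y")]
    return df[cols].to_numpy(dtype=float).reshape(-1, 68, 2)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, OBSERVATION_COLUMNS, path)
    _check_monotone(df, "frame_index", path)
    for c in ("eye_closed", "mouth_open", "valid"):
        df[c] = df[c].astype(bool)
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_features(path, require_label: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = FEATURE_COLUMNS_IO + (["label"] if require_label else [])
    _require(df, need, path)
    return df


def write_features(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_detections(path) -> list[FaceBox | None]:
    """Detection CSV -> per-frame boxes; empty coordinate fields mean
    the detector produced nothing for that frame."""
    df = pd.read_csv(path)
    _require(df, ["frame", "x1", "y1", "x2", "y2", "confidence"], path)
    out: list[FaceBox | None] = []
    for _, row in df.iterrows():
        if row[["x1", "y1", "x2", "y2"]].isna().any():
            out.append(None)
        else:
            conf = None if pd.isna(row["confidence"]) else float(row["confidence"])
            out.append(
                FaceBox(
                    float(row["x1"]), float(row["y1"]),
                    float(row["x2"]), float(row["y2"]),
                    confidence=conf, frame_index=int(row["frame"]),
                )
            )
    return out


def write_tracked(boxes, sources, path) -> None:
    pd.DataFrame(
        {
            "frame": [b.frame_index for b in boxes],
            "x1": [b.x1 for b in boxes],
            "y1": [b.y1 for b in boxes],
            "x2": [b.x2 for b in boxes],
            "y2": [b.y2 for b in boxes],
            "confidence": [b.confidence for b in boxes],
            "source": sources,
        }
    ).to_csv(path, index=False)


def write_decisions(decisions, path) -> None:
    """Per-window decision trace (segmented or whole-window)."""
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
    pd.DataFrame(rows).to_csv(path, index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config, seed: int, inputs: dict) -> None:
    """Reproducibility manifest: config, seed, input digests, version."""
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": asdict(config) if hasattr(config, "__dataclass_fields__") else config,
        "inputs": {name: _sha256(p) for name, p in inputs.items() if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
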