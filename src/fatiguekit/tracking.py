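"""Face bounding-box tracking with a constant-velocity Kalman filter.

Face detectors intermittently fail on in-cab video — the driver turns
away, a hand or the steering wheel occludes the face, or the detector's
confidence drops below a usable level.  To keep the downstream landmark
and feature pipeline fed with one box per frame, a Kalman filter tracks
the two box corners (top-left and bottom-right) and predicts through
detection gaps.

The state is 8-dimensional: the four corner coordinates (pixels, origin
top-left, x right / y down) and their per-frame velocities
(pixels/frame).  A constant-velocity transition keeps prediction through
gaps meaningful; with a measurement the filter performs the standard
predict/update cycle, without one it runs predict-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FaceBox",
    "KalmanBoxState",
    "TrackingError",
    "kalman_init",
    "kalman_step",
    "track_faces",
]

_DIM = 8  # (x1, y1, x2, y2, vx1, vy1, vx2, vy2)

# constant-velocity transition (dt = 1 frame) and position-only observation
_F = np.eye(_DIM)
_F[:4, 4:] = np.eye(4)
_H = np.zeros((4, _DIM))
_H[:4, :4] = np.eye(4)


class TrackingError(ValueError):
    """Raised when an input sequence cannot be tracked at all."""


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face box: top-left (x1, y1), bottom-right (x2, y2)."""

    x1: float
    y1: float
    x2: float
    y2: float
    confidence: float | None = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"degenerate box: need x1 < x2 and y1 < y2, got "
                f"({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def corners(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1


@dataclass
class KalmanBoxState:
    """Kalman state: mean vector, covariance, and the filter noise levels."""

    x: np.ndarray
    P: np.ndarray
    process_noise: float
    measurement_noise: float
    initialized: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.x.shape != (_DIM,) or self.P.shape != (_DIM, _DIM):
            raise ValueError("state must be 8-dim with 8x8 covariance")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("state vector must be finite")
        if not np.allclose(self.P, self.P.T):
            raise ValueError("covariance must be symmetric")


def kalman_init(
    box: FaceBox,
    process_noise: float = 1e-2,
    measurement_noise: float = 1.0,
    position_prior: float = 1.0,
    velocity_prior: float = 100.0,
) -> KalmanBoxState:
    """Initialize the tracker at ``box`` with zero velocity.

    ``velocity_prior`` is deliberately loose: velocities are unobserved
    at init and must be learned from the first few measurements.
    """
    if process_noise < 0 or measurement_noise < 0:
        raise ValueError("noise magnitudes must be non-negative")
    x = np.zeros(_DIM)
    x[:4] = box.corners
    P = np.diag([position_prior] * 4 + [velocity_prior] * 4).astype(float)
    return KalmanBoxState(
        x=x, P=P, process_noise=process_noise, measurement_noise=measurement_noise
    )


def _box_from_state(state: KalmanBoxState, frame_index: int = 0) -> FaceBox:
    x1, y1, x2, y2 = state.x[:4]
    # enforce corner ordering under long extrapolation: shrink toward the
    # box centre, never invert
    if x2 <= x1:
        cx = 0.5 * (x1 + x2)
        x1, x2 = cx - 0.5, cx + 0.5
    if y2 <= y1:
        cy = 0.5 * (y1 + y2)
        y1, y2 = cy - 0.5, cy + 0.5
    return FaceBox(x1, y1, x2, y2, frame_index=frame_index)


def kalman_step(
    state: KalmanBoxState,
    measurement: FaceBox | None = None,
) -> tuple[KalmanBoxState, FaceBox]:
    """One predict(+update) cycle; absent measurement means predict-only.

    Returns the new state and the filtered (or purely predicted) box.
    With measurement noise -> 0 the update pins the positions to the
    measurement exactly (pseudo-inverse handles the singular limit).
    """
    if not state.initialized:
        raise ValueError("state is not initialized")
    q, r = state.process_noise, state.measurement_noise

    x = _F @ state.x
    P = _F @ state.P @ _F.T + q * np.eye(_DIM)

    if measurement is not None:
        z = measurement.corners
        S = _H @ P @ _H.T + r * np.eye(4)
        K = P @ _H.T @ np.linalg.pinv(S)
        x = x + K @ (z - _H @ x)
        P = (np.eye(_DIM) - K @ _H) @ P
        P = 0.5 * (P + P.T)

    new = KalmanBoxState(
        x=x, P=P, process_noise=q, measurement_noise=r, initialized=True
    )
    frame = measurement.frame_index if measurement is not None else 0
    return new, _box_from_state(new, frame_index=frame)


def track_faces(
    detections: "list[FaceBox | None]",
    conf_threshold: float = 0.5,
    process_noise: float = 1e-2,
    measurement_noise: float = 1.0,
    max_coast_frames: int = 30,
) -> tuple[list[FaceBox], list[str]]:
    """Produce one box per frame, filling detection gaps by prediction.

    A detection is usable when present and its confidence is either
    absent (trusted) or >= ``conf_threshold``.  Unusable frames are
    filled with the Kalman prediction (``source == "predicted"``).
    Frames before the first usable detection are back-filled with the
    first filtered box.  After ``max_coast_frames`` consecutive
    predictions the track is declared lost: the box freezes until the
    next usable detection re-initializes the filter.

    Returns ``(boxes, sources)`` with ``sources[i]`` in
    ``{"measured", "predicted"}``.
    """
    if len(detections) == 0:
        raise TrackingError("empty detection sequence")

    def usable(det: FaceBox | None) -> bool:
        return det is not None and (
            det.confidence is None or det.confidence >= conf_threshold
        )

    if not any(usable(d) for d in detections):
        raise TrackingError("no usable detection in the entire sequence")

    boxes: list[FaceBox | None] = [None] * len(detections)
    sources = ["predicted"] * len(detections)
    state: KalmanBoxState | None = None
    coast = 0

    for i, det in enumerate(detections):
        if usable(det):
            if state is None or coast > max_coast_frames:
                if state is not None:
                    logger.info(
                        "track lost after %d coast frames; re-initializing at "
                        "frame %d",
                        coast,
                        i,
                    )
                state = kalman_init(det, process_noise, measurement_noise)
                box = _box_from_state(state, frame_index=i)
            else:
                state, box = kalman_step(state, det)
            coast = 0
            sources[i] = "measured"
        elif state is not None:
            coast += 1
            if coast > max_coast_frames:
                # frozen: hold the last box without further extrapolation
                box = boxes[i - 1]
            else:
                state, box = kalman_step(state, None)
            box = FaceBox(box.x1, box.y1, box.x2, box.y2, frame_index=i)
        else:
            continue  # leading gap, back-filled below
        boxes[i] = FaceBox(box.x1, box.y1, box.x2, box.y2, frame_index=i)

    first = next(i for i, b in enumerate(boxes) if b is not None)
    if first > 0:
        logger.info("back-filling %d frames before first usable detection", first)
        for i in range(first):
            b = boxes[first]
            boxes[i] = FaceBox(b.x1, b.y1, b.x2, b.y2, frame_index=i)
    return [b for b in boxes if b is not None], sources
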