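"""Per-frame eye and mouth openness from 68-point facial landmarks.

Two openness ratios drive the whole pipeline:

* EAR (eye aspect ratio): the mean vertical lid distance over the
  horizontal eye width, ``(|P2-P6| + |P3-P5|) / (2 |P1-P4|)``.  It is a
  similarity invariant of the six eye landmarks and collapses toward 0
  when the eye closes.
* MAR (mouth aspect ratio): the same functional form on six mouth
  landmarks; large during yawns.

Landmark-only EAR degrades under dim light, deep eye sockets or sloppy
landmark fits, so an image-processing variant is provided as well: crop
the eye region, denoise, Otsu-binarize so the eye pixels become 255,
correct the eye tilt, and measure the eye height as the maximum
per-column gray sum divided by 255.  EAR is then height / width with the
width taken from the eye-corner landmarks.

Landmark index conventions follow the iBUG 68-point markup: right eye
36-41, left eye 42-47, outer mouth corners 48/54 with upper lip 50/52
and lower lip 58/56.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "EyeLandmarks",
    "MouthLandmarks",
    "EyeCrop",
    "FrameObservation",
    "RIGHT_EYE",
    "LEFT_EYE",
    "MOUTH",
    "landmark_ear",
    "improved_ear",
    "mar",
    "classify_frame",
    "sweep_threshold",
    "eye_from_points",
    "mouth_from_points",
    "compute_observations",
]

DEFAULT_EAR_THRESHOLD = 0.21
DEFAULT_MAR_THRESHOLD = 0.4

# iBUG-68 indices mapped to the P1..P6 / M1..M6 roles
RIGHT_EYE = (36, 37, 38, 39, 40, 41)
LEFT_EYE = (42, 43, 44, 45, 46, 47)
MOUTH = (48, 50, 52, 54, 56, 58)


def _as_xy(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise ValueError("landmark must be a finite (x, y) pair")
    return a


@dataclass(frozen=True)
class EyeLandmarks:
    """Six eye landmarks: P1 outer corner, P2/P3 upper lid, P4 inner
    corner, P5/P6 lower lid (P6 below P2, P5 below P3)."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    p5: np.ndarray
    p6: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5", "p6"):
            object.__setattr__(self, name, _as_xy(getattr(self, name)))
        if np.linalg.norm(self.p1 - self.p4) == 0.0:
            raise ValueError("coincident eye corners P1 == P4")

    @property
    def width(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p4))


@dataclass(frozen=True)
class MouthLandmarks:
    """Six mouth landmarks: M1/M4 corners, M2/M3 upper lip, M6/M5 lower."""

    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray
    m4: np.ndarray
    m5: np.ndarray
    m6: np.ndarray

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "m3", "m4", "m5", "m6"):
            object.__setattr__(self, name, _as_xy(getattr(self, name)))
        if np.linalg.norm(self.m1 - self.m4) == 0.0:
            raise ValueError("coincident mouth corners M1 == M4")


@dataclass
class EyeCrop:
    """Intermediate result of the image-processing EAR.

    ``image`` is the tilt-corrected binary crop (eye pixels 255),
    ``rect`` the crop rectangle (x0, y0, x1, y1) in frame coordinates,
    ``column_sum_max`` the maximum per-column gray sum M, so the eye
    height is H = M / 255 and EAR = H / W.
    """

    image: np.ndarray
    rect: tuple[int, int, int, int]
    tilt_deg: float
    column_sum_max: float
    height: float
    width: float


@dataclass(frozen=True)
class FrameObservation:
    """One frame's openness measurements and binary states."""

    frame_index: int
    ear: float
    mar: float
    eye_closed: bool
    mouth_open: bool
    valid: bool = True
    timestamp: float = 0.0


def eye_from_points(points: np.ndarray, indices=RIGHT_EYE) -> EyeLandmarks:
    """Extract one eye from a (68, 2) landmark array."""
    pts = np.asarray(points, dtype=float)
    i1, i2, i3, i4, i5, i6 = indices
    return EyeLandmarks(pts[i1], pts[i2], pts[i3], pts[i4], pts[i5], pts[i6])


def mouth_from_points(points: np.ndarray, indices=MOUTH) -> MouthLandmarks:
    pts = np.asarray(points, dtype=float)
    i1, i2, i3, i4, i5, i6 = indices
    return MouthLandmarks(pts[i1], pts[i2], pts[i3], pts[i4], pts[i5], pts[i6])


def landmark_ear(eye: EyeLandmarks) -> float:
    """EAR = (|P2-P6| + |P3-P5|) / (2 |P1-P4|)."""
    v1 = np.linalg.norm(eye.p2 - eye.p6)
    v2 = np.linalg.norm(eye.p3 - eye.p5)
    return float((v1 + v2) / (2.0 * eye.width))


def mar(mouth: MouthLandmarks) -> float:
    """MAR = (|M2-M6| + |M3-M5|) / (2 |M1-M4|)."""
    v1 = np.linalg.norm(mouth.m2 - mouth.m6)
    v2 = np.linalg.norm(mouth.m3 - mouth.m5)
    h = np.linalg.norm(mouth.m1 - mouth.m4)
    return float((v1 + v2) / (2.0 * h))


def improved_ear(
    eye: EyeLandmarks,
    frame_image: np.ndarray,
    denoise_sigma: float = 1.0,
    polarity: str = "auto",
) -> tuple[float, EyeCrop]:
    """Image-processing EAR: crop, denoise, binarize, de-tilt, measure.

    Steps: (1) crop the bounding rectangle of the four lid landmarks
    P2, P3, P5, P6 extended by 50% of its height both up and down;
    (2) Gaussian denoise and Otsu-binarize with the eye-region class
    mapped to 255; (3) rotate the crop so the P1-P4 eye axis becomes
    horizontal (bilinear); (4) M = max per-column gray sum, H = M/255;
    (5) W = |P1 - P4|; (6) EAR = H / W.

    ``polarity``: "bright" maps the brighter Otsu class to 255, "dark"
    the darker one (typical for real iris/lash pixels against skin),
    "auto" the minority class — the eye occupies the smaller share of
    the extended crop either way.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame_image must be a 2-D grayscale array")
    if polarity not in ("auto", "bright", "dark"):
        raise ValueError(f"unknown polarity {polarity!r}")

    lids = np.stack([eye.p2, eye.p3, eye.p5, eye.p6])
    x0 = int(np.floor(lids[:, 0].min()))
    x1 = int(np.ceil(lids[:, 0].max()))
    ymin, ymax = lids[:, 1].min(), lids[:, 1].max()
    h = ymax - ymin
    y0 = int(np.floor(ymin - 0.5 * h))
    y1 = int(np.ceil(ymax + 0.5 * h))
    if x0 < 0 or y0 < 0 or x1 >= img.shape[1] or y1 >= img.shape[0]:
        raise ValueError(
            f"eye crop ({x0},{y0})-({x1},{y1}) extends outside the "
            f"{img.shape[1]}x{img.shape[0]} frame"
        )
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate eye crop")

    crop = img[y0 : y1 + 1, x0 : x1 + 1]
    smooth = ndimage.gaussian_filter(crop, sigma=denoise_sigma, truncate=2.0)

    if smooth.max() == smooth.min():
        binary = np.zeros_like(smooth, dtype=bool)  # featureless crop
    else:
        thr = threshold_otsu(smooth)
        bright = smooth > thr
        if polarity == "bright":
            binary = bright
        elif polarity == "dark":
            binary = ~bright
        else:
            binary = bright if bright.sum() <= (~bright).sum() else ~bright

    d = eye.p4 - eye.p1
    tilt = float(np.degrees(np.arctan2(d[1], d[0])))
    mapped = binary.astype(float) * 255.0
    if abs(tilt) > 1e-9:
        # rotate(+tilt) straightens an axis with image-coordinate angle
        # atan2(dy, dx); bilinear, expanded canvas so nothing is clipped
        mapped = ndimage.rotate(mapped, tilt, order=1, reshape=True)

    col_sums = mapped.sum(axis=0)
    m_val = float(col_sums.max()) if col_sums.size else 0.0
    height = m_val / 255.0
    width = eye.width
    if width == 0.0:
        raise ValueError("zero eye width")
    ear = height / width
    crop_out = EyeCrop(
        image=mapped,
        rect=(x0, y0, x1, y1),
        tilt_deg=tilt,
        column_sum_max=m_val,
        height=height,
        width=width,
    )
    return ear, crop_out


def classify_frame(
    ear: float,
    mar_value: float,
    ear_threshold: float = DEFAULT_EAR_THRESHOLD,
    mar_threshold: float = DEFAULT_MAR_THRESHOLD,
    frame_index: int = 0,
    timestamp: float = 0.0,
    valid: bool = True,
) -> FrameObservation:
    """Binary eye/mouth state: open requires strictly exceeding the
    threshold, so boundary equality counts closed for both."""
    if ear < 0 or mar_value < 0:
        raise ValueError("openness ratios must be non-negative")
    if ear_threshold <= 0 or mar_threshold <= 0:
        raise ValueError("thresholds must be positive")
    return FrameObservation(
        frame_index=frame_index,
        ear=float(ear),
        mar=float(mar_value),
        eye_closed=bool(ear <= ear_threshold),
        mouth_open=bool(mar_value > mar_threshold),
        valid=valid,
        timestamp=timestamp,
    )


def sweep_threshold(
    values,
    labels,
    grid,
) -> tuple[float, pd.DataFrame]:
    """Calibrate an openness threshold by accuracy sweep.

    For each grid point t, accuracy is the fraction of samples whose
    predicted state ``value > t`` matches ``label`` (True = open).
    Returns the accuracy-maximizing threshold (smallest on ties) and the
    full accuracy curve.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    grid = np.asarray(grid, dtype=float)
    if values.size == 0 or grid.size == 0:
        raise ValueError("values and grid must be non-empty")
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    acc = np.array([np.mean((values > t) == labels) for t in grid])
    best = float(grid[int(np.argmax(acc))])  # argmax returns first max
    curve = pd.DataFrame({"threshold": grid, "accuracy": acc})
    return best, curve


def compute_observations(
    points: np.ndarray,
    timestamps: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    ear_threshold: float = DEFAULT_EAR_THRESHOLD,
    mar_threshold: float = DEFAULT_MAR_THRESHOLD,
) -> pd.DataFrame:
    """Vectorized per-frame EAR/MAR over a (n, 68, 2) landmark stream.

    The per-frame EAR is the mean of the left- and right-eye EARs.
    Invalid frames get NaN ratios and closed==False placeholders; the
    temporal layer decides how to carry them.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 3 or pts.shape[1:] != (68, 2):
        raise ValueError("points must have shape (n_frames, 68, 2)")
    n = pts.shape[0]
    timestamps = (
        np.arange(n, dtype=float) if timestamps is None else np.asarray(timestamps)
    )
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)

    def _dist(a, b):
        return np.linalg.norm(pts[:, a] - pts[:, b], axis=1)

    def _eye_ear(idx):
        i1, i2, i3, i4, i5, i6 = idx
        return (_dist(i2, i6) + _dist(i3, i5)) / (2.0 * _dist(i1, i4))

    ear = 0.5 * (_eye_ear(RIGHT_EYE) + _eye_ear(LEFT_EYE))
    i1, i2, i3, i4, i5, i6 = MOUTH
    mar_v = (_dist(i2, i6) + _dist(i3, i5)) / (2.0 * _dist(i1, i4))

    ear = np.where(valid, ear, np.nan)
    mar_v = np.where(valid, mar_v, np.nan)
    return pd.DataFrame(
        {
            "frame_index": np.arange(n),
            "timestamp": timestamps,
            "ear": ear,
            "mar": mar_v,
            "eye_closed": np.where(valid, ear <= ear_threshold, False),
            "mouth_open": np.where(valid, mar_v > mar_threshold, False),
            "valid": valid,
        }
    )
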