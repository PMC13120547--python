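"""Kinematic signals, fall-phase segmentation and metric aggregation.

All quantities are computed in image coordinates (pixels, y-down), so
positive vertical velocity means the body is descending.  The mid-hip
landmark serves as the centre-of-mass proxy.  The instantaneous vertical
velocity is the first finite difference of mid-hip y scaled by the frame
rate (Δt = 1 frame), giving px/s; vertical acceleration is the second
difference scaled twice (px/s²).

The fall is segmented into pre-fall / impact / post-fall phases from the
sign structure of the (smoothed) vertical velocity: the impact phase is the
±200 ms window around the maximum-deceleration frame of the hips.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .pose_io import (
    COCO_KEYPOINTS,
    PoseFrame,
    TrackedSequence,
    landmark_arrays,
)


class KinematicsError(Exception):
    """Base class for kinematic computation failures."""


class InsufficientDataError(KinematicsError):
    """Fewer than two usable frames."""


class NoFallError(KinematicsError):
    """No frame exceeds the motion floor: no descent detected."""


class UndefinedAngleError(KinematicsError):
    """Trunk vector has zero length."""


@dataclass(frozen=True)
class KinematicsConfig:
    """Tunable parameters for metric extraction.

    ``smooth_window`` (frames) is the width of the centered moving average
    applied to landmark coordinates before differencing — second differences
    of raw pixel tracks at 60 fps are noise-dominated.  ``tau_move``
    (px/frame) is the per-frame mid-hip displacement above which a frame
    counts as "high movement"; most sequences never exceed it.
    ``motion_floor`` (px/s) gates fall detection.  ``impact_halfwidth_s`` is
    the half-width of the impact window around the deceleration peak.
    """

    smooth_window: int = 5
    motion_floor: float = 50.0
    tau_move: float = 15.0
    impact_halfwidth_s: float = 0.2


DEFAULT_CONFIG = KinematicsConfig()


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def _midhip_y(seq: TrackedSequence) -> np.ndarray:
    return landmark_arrays(seq)["mid_hip"][:, 1]


def vertical_velocity(seq: TrackedSequence) -> np.ndarray:
    """Raw vertical velocity of the mid-hip, px/s (positive = descending).

    ``vy[t] = (y_midhip[t] − y_midhip[t−1]) · fps``; NaN at frame 0 and
    wherever the mid-hip is undefined.
    """
    y = _midhip_y(seq)
    if np.sum(~np.isnan(y)) < 2:
        raise InsufficientDataError("need at least 2 frames with a defined mid-hip")
    vy = np.full(y.shape, np.nan)
    vy[1:] = np.diff(y) * seq.fps
    return vy


def vertical_acceleration(seq: TrackedSequence) -> np.ndarray:
    """Second finite difference of mid-hip y, px/s²; NaN for the first two frames."""
    vy = vertical_velocity(seq)
    ay = np.full(vy.shape, np.nan)
    ay[1:] = np.diff(vy) * seq.fps
    return ay


def trunk_inclination(frame: PoseFrame) -> float:
    """Angle (degrees, 0–180) between the vertical axis and the hip→shoulder vector.

    0° means the mid-shoulder sits directly above the mid-hip (upright);
    90° means the trunk is horizontal.
    """
    from .pose_io import derive_landmarks

    lm = derive_landmarks(frame)
    if lm.mid_hip is None or lm.mid_shoulder is None:
        raise KinematicsError("hips and shoulders must be visible")
    vx = lm.mid_shoulder[0] - lm.mid_hip[0]
    vy = lm.mid_shoulder[1] - lm.mid_hip[1]
    norm = float(np.hypot(vx, vy))
    if norm == 0.0:
        raise UndefinedAngleError("mid-hip and mid-shoulder coincide")
    # vertical "up" in image coordinates is (0, -1)
    cosang = np.clip(-vy / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def aspect_ratio(frame: PoseFrame) -> float:
    """Bounding-box width / height; AR > 1 typically indicates a lying pose."""
    _, _, w, h = frame.bbox
    if h <= 0:
        raise ZeroDivisionError("bbox height must be > 0")
    return float(w / h)


def _trunk_angle_series(seq: TrackedSequence) -> np.ndarray:
    lm = landmark_arrays(seq)
    v = lm["mid_shoulder"] - lm["mid_hip"]
    norm = np.hypot(v[:, 0], v[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(-v[:, 1] / norm, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
    ang[norm == 0] = np.nan
    return ang


def _neck_distance_series(seq: TrackedSequence) -> np.ndarray:
    lm = landmark_arrays(seq)
    d = lm["chin_proxy"] - lm["sternum_proxy"]
    return np.hypot(d[:, 0], d[:, 1])


def _aspect_ratio_series(seq: TrackedSequence) -> np.ndarray:
    return seq.bbox[:, 2] / seq.bbox[:, 3]


@dataclass(frozen=True)
class KinematicSeries:
    """Per-frame kinematic signals for one sequence."""

    t: np.ndarray  # frame indices
    vy: np.ndarray  # px/s, positive = descending
    ay: np.ndarray  # px/s²
    speed: np.ndarray  # planar mid-hip speed, px/s
    trunk_angle: np.ndarray  # degrees from vertical
    aspect_ratio: np.ndarray  # unitless
    neck_distance: np.ndarray  # px


def compute_series(seq: TrackedSequence) -> KinematicSeries:
    """Raw (unsmoothed) per-frame signal bundle."""
    lm = landmark_arrays(seq)["mid_hip"]
    vy = vertical_velocity(seq)
    ay = np.full(vy.shape, np.nan)
    ay[1:] = np.diff(vy) * seq.fps
    disp = np.full(lm.shape, np.nan)
    disp[1:] = np.diff(lm, axis=0)
    speed = np.hypot(disp[:, 0], disp[:, 1]) * seq.fps
    return KinematicSeries(
        t=seq.frame_index.copy(),
        vy=vy,
        ay=ay,
        speed=speed,
        trunk_angle=_trunk_angle_series(seq),
        aspect_ratio=_aspect_ratio_series(seq),
        neck_distance=_neck_distance_series(seq),
    )


# ---------------------------------------------------------------------------
# Phase segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open frame intervals for the three fall phases."""

    pre_fall: tuple[int, int]
    impact: tuple[int, int]
    post_fall: tuple[int, int]
    peak_decel_frame: int

    def __post_init__(self) -> None:
        assert self.pre_fall[1] == self.impact[0] <= self.peak_decel_frame
        assert self.impact[1] == self.post_fall[0]


def segment_phases(
    seq: TrackedSequence,
    smooth_window: int = 5,
    motion_floor: float = 50.0,
    impact_halfwidth_s: float = 0.2,
) -> PhaseSegmentation:
    """Segment pre-fall / impact / post-fall phases.

    The vertical velocity is smoothed with a centered moving average; the
    descent episode is the contiguous run above ``motion_floor`` containing
    the velocity maximum, extended outward to the nearest zero crossings.
    The peak-deceleration frame is the argmax of −ay (first index on ties)
    within that episode, and the impact phase spans ±``impact_halfwidth_s``
    around it, clipped at the sequence bounds.  For a constant-velocity
    descent (zero interior acceleration) the convention yields the first
    episode frame.
    """
    vy = vertical_velocity(seq)
    n = vy.shape[0]
    vys = _smooth(vy, smooth_window)
    if not np.any(np.nan_to_num(vys, nan=-np.inf) > motion_floor):
        raise NoFallError(
            f"no smoothed vertical velocity exceeds the motion floor ({motion_floor} px/s)"
        )
    peak_v = int(np.nanargmax(vys))
    pos = np.nan_to_num(vys, nan=0.0) > 0
    lo = peak_v
    while lo > 1 and pos[lo - 1]:
        lo -= 1
    hi = peak_v
    while hi < n - 1 and pos[hi + 1]:
        hi += 1
    ays = np.full(n, np.nan)
    ays[1:] = np.diff(vys) * seq.fps
    window = -ays[lo : hi + 1]
    if np.all(np.isnan(window)):
        peak = lo
    else:
        peak = lo + int(np.nanargmax(window))
    half = int(round(impact_halfwidth_s * seq.fps))
    start = max(0, peak - half)
    end = min(n, peak + half + 1)
    return PhaseSegmentation(
        pre_fall=(0, start),
        impact=(start, end),
        post_fall=(end, n),
        peak_decel_frame=peak,
    )


# ---------------------------------------------------------------------------
# Sequence-level metrics
# ---------------------------------------------------------------------------

#: The 15 sequence-level kinematic descriptors, in canonical order.
METRIC_NAMES: tuple[str, ...] = (
    "avg_velocity",
    "max_velocity",
    "avg_acceleration",
    "max_acceleration",
    "movement_range_x",
    "movement_range_y",
    "position_variability_x",
    "position_variability_y",
    "velocity_variability",
    "max_descent_rate",
    "avg_descent_rate",
    "total_vertical_change",
    "high_movement_frames",
    "movement_intensity",
    "avg_confidence",
)

POSTURAL_NAMES: tuple[str, ...] = (
    "mean_trunk_angle",
    "max_aspect_ratio",
    "min_neck_distance",
)

#: Category tags for the 15 metrics: fall commitment, postural stability,
#: general movement.
METRIC_CATEGORIES: dict[str, str] = {
    "avg_descent_rate": "fall",
    "max_descent_rate": "fall",
    "total_vertical_change": "fall",
    "position_variability_x": "stability",
    "position_variability_y": "stability",
    "velocity_variability": "stability",
    **{
        name: "movement"
        for name in METRIC_NAMES
        if name
        not in {
            "avg_descent_rate",
            "max_descent_rate",
            "total_vertical_change",
            "position_variability_x",
            "position_variability_y",
            "velocity_variability",
        }
    },
}


@dataclass(frozen=True)
class MetricVector:
    """Sequence-level kinematic descriptors (15 core + 3 postural)."""

    avg_velocity: float
    max_velocity: float
    avg_acceleration: float
    max_acceleration: float
    movement_range_x: float
    movement_range_y: float
    position_variability_x: float
    position_variability_y: float
    velocity_variability: float
    max_descent_rate: float
    avg_descent_rate: float
    total_vertical_change: float
    high_movement_frames: float
    movement_intensity: float
    avg_confidence: float
    mean_trunk_angle: float
    max_aspect_ratio: float
    min_neck_distance: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _nan0(x: float) -> float:
    return 0.0 if np.isnan(x) else float(x)


def extract_metrics(
    seq: TrackedSequence, config: KinematicsConfig = DEFAULT_CONFIG
) -> MetricVector:
    """Aggregate the metric vector over the full fall episode.

    The aggregation window is the whole segmented episode (pre-fall start
    through post-fall end), i.e. the full sequence.  Velocities and
    accelerations are computed from landmark coordinates smoothed with a
    centered moving average (``config.smooth_window``); positional ranges
    and variabilities use the raw coordinates.
    """
    hip = landmark_arrays(seq)["mid_hip"]
    if np.sum(~np.isnan(hip[:, 0])) < 2:
        raise InsufficientDataError("need at least 2 frames with a defined mid-hip")
    fps = seq.fps

    sx = _smooth(hip[:, 0], config.smooth_window)
    sy = _smooth(hip[:, 1], config.smooth_window)
    dvec = np.stack([np.diff(sx), np.diff(sy)], axis=1)  # px/frame
    speed = np.hypot(dvec[:, 0], dvec[:, 1]) * fps
    accel_vec = np.diff(dvec, axis=0) * fps * fps
    accel = np.hypot(accel_vec[:, 0], accel_vec[:, 1])
    vy_s = np.diff(sy) * fps
    descent = np.clip(vy_s, 0.0, None)

    raw_disp = np.hypot(np.diff(hip[:, 0]), np.diff(hip[:, 1]))  # px/frame
    high = raw_disp[raw_disp > config.tau_move]

    with np.errstate(invalid="ignore"):
        mv = MetricVector(
            avg_velocity=_nan0(np.nanmean(speed)) if speed.size else 0.0,
            max_velocity=_nan0(np.nanmax(speed)) if speed.size else 0.0,
            avg_acceleration=_nan0(np.nanmean(accel)) if accel.size else 0.0,
            max_acceleration=_nan0(np.nanmax(accel)) if accel.size else 0.0,
            movement_range_x=_nan0(np.nanmax(hip[:, 0]) - np.nanmin(hip[:, 0])),
            movement_range_y=_nan0(np.nanmax(hip[:, 1]) - np.nanmin(hip[:, 1])),
            position_variability_x=_nan0(np.nanstd(hip[:, 0])),
            position_variability_y=_nan0(np.nanstd(hip[:, 1])),
            velocity_variability=_nan0(np.nanstd(speed)) if speed.size else 0.0,
            max_descent_rate=_nan0(np.nanmax(descent)) if descent.size else 0.0,
            avg_descent_rate=_nan0(np.nanmean(descent)) if descent.size else 0.0,
            total_vertical_change=_nan0(np.nanmax(hip[:, 1]) - np.nanmin(hip[:, 1])),
            high_movement_frames=float(high.size),
            movement_intensity=float(np.mean(high)) if high.size else 0.0,
            avg_confidence=float(np.mean(seq.keypoints[:, :, 2])),
            mean_trunk_angle=_nan0(np.nanmean(_trunk_angle_series(seq))),
            max_aspect_ratio=_nan0(np.nanmax(_aspect_ratio_series(seq))),
            min_neck_distance=_nan0(np.nanmin(_neck_distance_series(seq))),
        )
    return mv


def extract_metrics_table(
    seqs: Sequence[TrackedSequence], config: KinematicsConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Metric vectors for a collection of sequences as a tidy table."""
    rows = []
    for seq in seqs:
        row = {
            "subject_id": seq.subject_id,
            "cohort": seq.cohort,
            "quality_label": seq.quality_label,
            "profile": seq.meta.get("profile"),
        }
        row.update(extract_metrics(seq, config).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frame-level feature matrix
# ---------------------------------------------------------------------------

FEATURE_SCHEMA_VERSION = 1

_LANDMARKS = ("mid_hip", "mid_shoulder", "chin_proxy", "sternum_proxy")


def frame_feature_columns() -> list[str]:
    """The documented, versioned column schema of the frame feature matrix."""
    cols: list[str] = []
    coord_cols: list[str] = []
    for name in COCO_KEYPOINTS:
        cols += [f"{name}_x", f"{name}_y", f"{name}_conf"]
        coord_cols += [f"{name}_x", f"{name}_y"]
    for name in _LANDMARKS:
        cols += [f"{name}_x", f"{name}_y"]
        coord_cols += [f"{name}_x", f"{name}_y"]
    cols += [f"d_{c}" for c in coord_cols]
    cols += [f"dd_{c}" for c in coord_cols]
    cols += [
        "trunk_angle",
        "aspect_ratio",
        "neck_distance",
        "d_trunk_angle",
        "d_aspect_ratio",
        "d_neck_distance",
        "centroid_disp",
    ]
    return cols


def extract_frame_features(seq: TrackedSequence) -> pd.DataFrame:
    """Frame-level feature expansion used for supervised classification.

    One row per frame: raw keypoint coordinates and confidences, derived
    landmark coordinates, first and second temporal derivatives (raw finite
    differences scaled by fps) of every coordinate, postural signals with
    their first derivatives, and the per-frame centroid displacement
    (px/frame).  Boundary rows where a derivative is undefined hold NaN.
    """
    n = seq.n_frames
    fps = seq.fps
    data: dict[str, np.ndarray] = {}
    coord_arrays: list[tuple[str, np.ndarray]] = []
    for k, name in enumerate(COCO_KEYPOINTS):
        data[f"{name}_x"] = seq.keypoints[:, k, 0]
        data[f"{name}_y"] = seq.keypoints[:, k, 1]
        data[f"{name}_conf"] = seq.keypoints[:, k, 2]
        coord_arrays.append((f"{name}_x", seq.keypoints[:, k, 0]))
        coord_arrays.append((f"{name}_y", seq.keypoints[:, k, 1]))
    lms = landmark_arrays(seq)
    for name in _LANDMARKS:
        data[f"{name}_x"] = lms[name][:, 0]
        data[f"{name}_y"] = lms[name][:, 1]
        coord_arrays.append((f"{name}_x", lms[name][:, 0]))
        coord_arrays.append((f"{name}_y", lms[name][:, 1]))

    def d1(x: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        out[1:] = np.diff(np.asarray(x, dtype=float)) * fps
        return out

    for name, arr in coord_arrays:
        data[f"d_{name}"] = d1(arr)
    for name, arr in coord_arrays:
        data[f"dd_{name}"] = d1(data[f"d_{name}"])

    trunk = _trunk_angle_series(seq)
    ar = _aspect_ratio_series(seq)
    neck = _neck_distance_series(seq)
    data["trunk_angle"] = trunk
    data["aspect_ratio"] = ar
    data["neck_distance"] = neck
    data["d_trunk_angle"] = d1(trunk)
    data["d_aspect_ratio"] = d1(ar)
    data["d_neck_distance"] = d1(neck)

    centroid = seq.keypoints[:, :, :2].mean(axis=1)
    disp = np.full(n, np.nan)
    disp[1:] = np.hypot(*np.diff(centroid, axis=0).T)
    data["centroid_disp"] = disp

    df = pd.DataFrame(data, columns=frame_feature_columns())
    df.insert(0, "frame_index", seq.frame_index)
    return df


def frame_feature_table(
    seqs: Sequence[TrackedSequence], stride: int = 1
) -> pd.DataFrame:
    """Concatenated frame features for many sequences, with identity columns.

    ``stride`` subsamples frames (every ``stride``-th row) to bound the size
    of large cohorts.
    """
    parts = []
    for seq in seqs:
        df = extract_frame_features(seq)
        if stride > 1:
            df = df.iloc[::stride]
        df.insert(0, "subject_id", seq.subject_id)
        df.insert(1, "cohort", seq.cohort)
        df.insert(2, "quality_label", seq.quality_label)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)
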