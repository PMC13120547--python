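"""Reading, validating, repairing and writing tracked 2D skeleton sequences.

The on-disk format is a documented JSON dialect (``data/pose_schema.json``)
emulating the structured output of a detection → segmentation → tracking →
pose-estimation pipeline: one record per tracked identity, each holding
per-frame COCO-17 keypoints ``(x, y, confidence)``, a bounding box and a
visibility mask.  Image coordinates have their origin at the top-left with y
increasing downward, so *descent* means increasing y.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: COCO keypoint order used throughout the package.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

N_KEYPOINTS = 17

KP_INDEX = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

COHORTS = ("pre", "post", "unknown")
QUALITY_LABELS = ("safe", "hazardous")

SCHEMA_FORMAT = "safefall-pose"
SCHEMA_VERSION = 1


class PoseIOError(Exception):
    """Base class for pose I/O failures."""


class PoseSchemaError(PoseIOError):
    """The file parsed as JSON but violates the pose schema."""


class PoseParseError(PoseIOError):
    """The file is not parseable JSON."""


@dataclass(frozen=True)
class Keypoint:
    """A single 2D keypoint in image coordinates (pixels, y-down)."""

    x: float
    y: float
    confidence: float


@dataclass(frozen=True)
class DerivedLandmarks:
    """Convex-combination landmarks derived from the COCO-17 set.

    Each entry is an ``(x, y)`` tuple or ``None`` when any source keypoint is
    invisible for the frame.  ``chin_proxy`` is the nose keypoint and
    ``sternum_proxy`` the shoulder midpoint: COCO-17 carries neither a chin
    nor a sternum point, and these are the closest stable anatomical proxies.
    """

    mid_hip: tuple[float, float] | None
    mid_shoulder: tuple[float, float] | None
    chin_proxy: tuple[float, float] | None
    sternum_proxy: tuple[float, float] | None


class PoseFrame:
    """Read-only view of one frame of a :class:`TrackedSequence`."""

    __slots__ = ("_seq", "_i")

    def __init__(self, seq: "TrackedSequence", i: int):
        self._seq = seq
        self._i = i

    @property
    def frame_index(self) -> int:
        return int(self._seq.frame_index[self._i])

    @property
    def keypoints(self) -> list[Keypoint]:
        arr = self._seq.keypoints[self._i]
        return [Keypoint(float(x), float(y), float(c)) for x, y, c in arr]

    @property
    def keypoint_array(self) -> np.ndarray:
        """(17, 3) array of x, y, confidence."""
        return self._seq.keypoints[self._i]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return tuple(float(v) for v in self._seq.bbox[self._i])

    @property
    def visibility_mask(self) -> np.ndarray:
        return self._seq.visibility[self._i]


@dataclass
class TrackedSequence:
    """One tracked identity's time-ordered pose frames.

    Frames are stored column-wise in numpy arrays for speed; :attr:`frames`
    yields per-frame views.
    """

    subject_id: str
    track_id: int
    fps: float
    frame_size: tuple[int, int]  # (width, height) pixels
    frame_index: np.ndarray  # (n,) int
    keypoints: np.ndarray  # (n, 17, 3) float: x, y, confidence
    visibility: np.ndarray  # (n, 17) bool
    bbox: np.ndarray  # (n, 4) float: x_min, y_min, width, height
    cohort: str = "unknown"
    quality_label: str | None = None
    imputed: np.ndarray | None = None  # (n, 17) bool, set by repair_gaps
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        self.bbox = np.asarray(self.bbox, dtype=np.float64)
        if self.imputed is None:
            self.imputed = np.zeros_like(self.visibility)
        validate_sequence(self)

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.shape[0])

    @property
    def frames(self) -> list[PoseFrame]:
        return [PoseFrame(self, i) for i in range(self.n_frames)]

    def __iter__(self) -> Iterator[PoseFrame]:
        return iter(self.frames)

    def copy(self) -> "TrackedSequence":
        return replace(
            self,
            frame_index=self.frame_index.copy(),
            keypoints=self.keypoints.copy(),
            visibility=self.visibility.copy(),
            bbox=self.bbox.copy(),
            imputed=self.imputed.copy(),
            meta=dict(self.meta),
        )


def validate_sequence(seq: TrackedSequence) -> None:
    """Check TrackedSequence invariants; raise :class:`PoseSchemaError`."""
    n = seq.frame_index.shape[0]
    if seq.keypoints.shape != (n, N_KEYPOINTS, 3):
        raise PoseSchemaError(
            f"sequence {seq.subject_id!r}: keypoints shape "
            f"{seq.keypoints.shape} != ({n}, {N_KEYPOINTS}, 3)"
        )
    if seq.visibility.shape != (n, N_KEYPOINTS):
        raise PoseSchemaError(f"sequence {seq.subject_id!r}: bad visibility shape")
    if seq.bbox.shape != (n, 4):
        raise PoseSchemaError(f"sequence {seq.subject_id!r}: bad bbox shape")
    if seq.fps <= 0:
        raise PoseSchemaError(f"sequence {seq.subject_id!r}: fps must be > 0")
    if n > 1 and not np.all(np.diff(seq.frame_index) > 0):
        raise PoseSchemaError(
            f"sequence {seq.subject_id!r}: frame_index not strictly increasing"
        )
    if n and (np.any(seq.bbox[:, 2] <= 0) or np.any(seq.bbox[:, 3] <= 0)):
        raise PoseSchemaError(
            f"sequence {seq.subject_id!r}: bbox width/height must be > 0"
        )
    if seq.cohort not in COHORTS:
        raise PoseSchemaError(f"sequence {seq.subject_id!r}: bad cohort {seq.cohort!r}")
    if seq.quality_label is not None and seq.quality_label not in QUALITY_LABELS:
        raise PoseSchemaError(
            f"sequence {seq.subject_id!r}: bad quality_label {seq.quality_label!r}"
        )
    conf = seq.keypoints[:, :, 2]
    if n and (np.any(conf < 0) or np.any(conf > 1)):
        raise PoseSchemaError(
            f"sequence {seq.subject_id!r}: keypoint confidence outside [0, 1]"
        )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def _seq_to_record(seq: TrackedSequence) -> dict:
    frames = []
    for i in range(seq.n_frames):
        frames.append(
            {
                "frame_index": int(seq.frame_index[i]),
                "bbox": [float(v) for v in seq.bbox[i]],
                "keypoints": [[float(v) for v in kp] for kp in seq.keypoints[i]],
                "visible": [bool(v) for v in seq.visibility[i]],
                "imputed": [bool(v) for v in seq.imputed[i]],
            }
        )
    return {
        "subject_id": seq.subject_id,
        "track_id": int(seq.track_id),
        "fps": float(seq.fps),
        "frame_size": [int(seq.frame_size[0]), int(seq.frame_size[1])],
        "cohort": seq.cohort,
        "quality_label": seq.quality_label,
        "meta": seq.meta,
        "frames": frames,
    }


def _record_to_seq(rec: dict, *, clamp: bool = True) -> TrackedSequence:
    try:
        subject_id = str(rec["subject_id"])
        frames = rec["frames"]
        fps = float(rec["fps"])
        width, height = (int(v) for v in rec["frame_size"])
    except (KeyError, TypeError, ValueError) as exc:
        raise PoseSchemaError(f"malformed identity record: {exc}") from exc

    n = len(frames)
    frame_index = np.empty(n, dtype=np.int64)
    kps = np.empty((n, N_KEYPOINTS, 3), dtype=np.float64)
    vis = np.ones((n, N_KEYPOINTS), dtype=bool)
    imp = np.zeros((n, N_KEYPOINTS), dtype=bool)
    bbox = np.empty((n, 4), dtype=np.float64)
    for i, fr in enumerate(frames):
        try:
            frame_index[i] = int(fr["frame_index"])
            kp = np.asarray(fr["keypoints"], dtype=np.float64)
            bbox[i] = np.asarray(fr["bbox"], dtype=np.float64)
        except (KeyError, TypeError, ValueError) as exc:
            raise PoseSchemaError(
                f"sequence {subject_id!r}, frame {i}: malformed record ({exc})"
            ) from exc
        if kp.shape != (N_KEYPOINTS, 3):
            raise PoseSchemaError(
                f"sequence {subject_id!r}, frame {i}: expected {N_KEYPOINTS} "
                f"keypoints, got shape {kp.shape}"
            )
        kps[i] = kp
        if "visible" in fr:
            vis[i] = np.asarray(fr["visible"], dtype=bool)
        if "imputed" in fr:
            imp[i] = np.asarray(fr["imputed"], dtype=bool)

    if clamp and n:
        conf = kps[:, :, 2]
        n_bad = int(np.sum((conf < 0) | (conf > 1)))
        if n_bad:
            logger.warning(
                "sequence %r: clamped %d out-of-range confidence value(s) to [0, 1]",
                subject_id,
                n_bad,
            )
            np.clip(conf, 0.0, 1.0, out=conf)
        xy = kps[:, :, :2]
        n_oob = int(np.sum((xy[..., 0] < 0) | (xy[..., 0] > width)
                           | (xy[..., 1] < 0) | (xy[..., 1] > height)))
        if n_oob:
            logger.warning(
                "sequence %r: clamped %d keypoint coordinate(s) to the frame",
                subject_id,
                n_oob,
            )
            np.clip(xy[..., 0], 0.0, width, out=xy[..., 0])
            np.clip(xy[..., 1], 0.0, height, out=xy[..., 1])

    return TrackedSequence(
        subject_id=subject_id,
        track_id=int(rec.get("track_id", 0)),
        fps=fps,
        frame_size=(width, height),
        frame_index=frame_index,
        keypoints=kps,
        visibility=vis,
        bbox=bbox,
        cohort=str(rec.get("cohort") or "unknown"),
        quality_label=rec.get("quality_label"),
        imputed=imp,
        meta=dict(rec.get("meta") or {}),
    )


def read_sequences(path: str | Path) -> list[TrackedSequence]:
    """Read tracked sequences from the pose-JSON dialect.

    Out-of-range confidences and coordinates are clamped with a logged
    warning; structural violations (wrong keypoint count, bad bbox) raise
    :class:`PoseSchemaError` naming the offending record.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PoseParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format") != SCHEMA_FORMAT:
        raise PoseSchemaError(f"{path}: missing format marker {SCHEMA_FORMAT!r}")
    return [_record_to_seq(rec) for rec in payload.get("sequences", [])]


def write_sequences(seqs: Sequence[TrackedSequence], path: str | Path) -> None:
    """Write sequences to the pose-JSON dialect.

    Output is byte-stable: keys are sorted and floats use their shortest
    round-trippable representation, so ``read ∘ write`` is the identity on the
    data model and serializing twice yields identical bytes.
    """
    payload = {
        "format": SCHEMA_FORMAT,
        "version": SCHEMA_VERSION,
        "sequences": [_seq_to_record(s) for s in seqs],
    }
    text = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    Path(path).write_text(text)


def sequences_equal(a: TrackedSequence, b: TrackedSequence) -> bool:
    """Structural equality on the data model (exact float comparison)."""
    return (
        a.subject_id == b.subject_id
        and a.track_id == b.track_id
        and a.fps == b.fps
        and tuple(a.frame_size) == tuple(b.frame_size)
        and a.cohort == b.cohort
        and a.quality_label == b.quality_label
        and np.array_equal(a.frame_index, b.frame_index)
        and np.array_equal(a.keypoints, b.keypoints)
        and np.array_equal(a.visibility, b.visibility)
        and np.array_equal(a.bbox, b.bbox)
        and np.array_equal(a.imputed, b.imputed)
        and a.meta == b.meta
    )


# ---------------------------------------------------------------------------
# Gap repair
# ---------------------------------------------------------------------------


def repair_gaps(
    seq: TrackedSequence, conf_floor: float = 0.5, max_gap: int = 10
) -> TrackedSequence:
    """Mask low-confidence keypoints and interpolate short invisible runs.

    Keypoints with confidence below ``conf_floor`` are marked invisible.
    Invisible runs of length ≤ ``max_gap`` frames bounded by visible frames on
    both sides are linearly interpolated per coordinate and flagged in
    ``imputed``; longer runs and runs touching either end of the sequence stay
    masked (endpoints are never extrapolated).  Idempotent; frames whose
    keypoints were all visible are untouched.
    """
    out = seq.copy()
    # already-imputed points keep their repaired coordinates: makes the
    # operation idempotent even though their confidence stays low
    vis = (out.visibility & (out.keypoints[:, :, 2] >= conf_floor)) | out.imputed
    n = out.n_frames
    for k in range(N_KEYPOINTS):
        v = vis[:, k]
        if v.all() or not v.any():
            continue
        idx = np.flatnonzero(~v)
        # split invisible indices into contiguous runs
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            lo, hi = run[0], run[-1]
            if lo == 0 or hi == n - 1 or len(run) > max_gap:
                continue
            x0, y0 = out.keypoints[lo - 1, k, :2]
            x1, y1 = out.keypoints[hi + 1, k, :2]
            # interpolate on frame_index to honour any gaps in numbering
            t0, t1 = out.frame_index[lo - 1], out.frame_index[hi + 1]
            w = (out.frame_index[run] - t0) / (t1 - t0)
            out.keypoints[run, k, 0] = x0 + w * (x1 - x0)
            out.keypoints[run, k, 1] = y0 + w * (y1 - y0)
            v[run] = True
            out.imputed[run, k] = True
    out.visibility = vis
    return out


# ---------------------------------------------------------------------------
# Derived landmarks
# ---------------------------------------------------------------------------

_L_HIP, _R_HIP = KP_INDEX["left_hip"], KP_INDEX["right_hip"]
_L_SH, _R_SH = KP_INDEX["left_shoulder"], KP_INDEX["right_shoulder"]
_NOSE = KP_INDEX["nose"]


def derive_landmarks(frame: PoseFrame) -> DerivedLandmarks:
    """Mid-hip, mid-shoulder, chin and sternum proxies for one frame."""
    kp = frame.keypoint_array
    vis = frame.visibility_mask

    def _mid(i: int, j: int) -> tuple[float, float] | None:
        if vis[i] and vis[j]:
            return (
                float((kp[i, 0] + kp[j, 0]) / 2.0),
                float((kp[i, 1] + kp[j, 1]) / 2.0),
            )
        return None

    mid_shoulder = _mid(_L_SH, _R_SH)
    return DerivedLandmarks(
        mid_hip=_mid(_L_HIP, _R_HIP),
        mid_shoulder=mid_shoulder,
        chin_proxy=(float(kp[_NOSE, 0]), float(kp[_NOSE, 1])) if vis[_NOSE] else None,
        sternum_proxy=mid_shoulder,
    )


def landmark_arrays(seq: TrackedSequence) -> dict[str, np.ndarray]:
    """Vectorized landmark series for a whole sequence.

    Returns ``{name: (n, 2) array}`` with NaN rows where a source keypoint is
    invisible.
    """
    kp = seq.keypoints[:, :, :2]
    vis = seq.visibility
    out: dict[str, np.ndarray] = {}

    def _mid(i: int, j: int) -> np.ndarray:
        m = (kp[:, i] + kp[:, j]) / 2.0
        bad = ~(vis[:, i] & vis[:, j])
        m = m.copy()
        m[bad] = np.nan
        return m

    out["mid_hip"] = _mid(_L_HIP, _R_HIP)
    out["mid_shoulder"] = _mid(_L_SH, _R_SH)
    nose = kp[:, _NOSE].copy()
    nose[~vis[:, _NOSE]] = np.nan
    out["chin_proxy"] = nose
    out["sternum_proxy"] = out["mid_shoulder"].copy()
    return out


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------


def to_dataframe(seqs: Sequence[TrackedSequence]) -> pd.DataFrame:
    """Flatten sequences to a long keypoint table (one row per frame)."""
    rows = []
    for seq in seqs:
        for i in range(seq.n_frames):
            row: dict = {
                "subject_id": seq.subject_id,
                "track_id": seq.track_id,
                "cohort": seq.cohort,
                "frame_index": int(seq.frame_index[i]),
            }
            for k, name in enumerate(COCO_KEYPOINTS):
                row[f"{name}_x"] = seq.keypoints[i, k, 0]
                row[f"{name}_y"] = seq.keypoints[i, k, 1]
                row[f"{name}_conf"] = seq.keypoints[i, k, 2]
                row[f"{name}_visible"] = bool(seq.visibility[i, k])
            row["bbox_x"], row["bbox_y"], row["bbox_w"], row["bbox_h"] = seq.bbox[i]
            rows.append(row)
    return pd.DataFrame(rows)
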