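"""Readers and writers for pose results, frame labels, and feature tables.

Pose results follow the AlphaPose single-file convention: a JSON list of
records, one per detected person per frame, each holding an image
identifier, a flat list of 51 keypoint numbers (17 joints x (x, y, score)
in COCO order) and an overall detection score.  Frame labels are a CSV with
header ``frame,label``; feature tables are CSV with header
``label,f0,...,f{F-1}``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: joints per skeleton in the COCO keypoint convention
N_KEYPOINTS = 17
#: values per skeleton: 17 joints x (x, y, score)
FEATURES_PER_SKELETON = 3 * N_KEYPOINTS

#: activity label vocabulary: ids 1-5 are fall classes, 6-12 daily activities
DEFAULT_VOCABULARY = tuple(range(1, 13))

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an external file violates its declared format."""


@dataclass(frozen=True)
class PoseDetection:
    """One person's skeleton in one frame: 17 keypoints plus overall score.

    ``keypoints`` is a (17, 3) array of (x, y, s) rows in COCO joint order;
    joint scores s lie in [0, 1].  ``flat`` exposes the same values as the
    51-vector (x1, y1, s1, ..., x17, y17, s17) used as per-frame features.
    """

    keypoints: np.ndarray
    overall_score: float

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (N_KEYPOINTS, 3):
            raise ValueError(f"expected (17, 3) keypoints, got shape {kp.shape}")
        if not np.all(np.isfinite(kp[:, :2])):
            raise ValueError("keypoint coordinates must be finite")
        scores = kp[:, 2]
        if np.any(scores < 0) or np.any(scores > 1):
            logger.warning("joint scores outside [0, 1] clamped")
            kp = kp.copy()
            kp[:, 2] = np.clip(scores, 0.0, 1.0)
        if self.overall_score < 0:
            raise ValueError("overall_score must be non-negative")
        kp.setflags(write=False)
        object.__setattr__(self, "keypoints", kp)

    @property
    def flat(self) -> np.ndarray:
        """The 51-value feature view, a pure reordering of the keypoints."""
        return self.keypoints.reshape(-1)

    @classmethod
    def from_flat(cls, values: Sequence[float], overall_score: float) -> "PoseDetection":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (FEATURES_PER_SKELETON,):
            raise ValueError(f"expected {FEATURES_PER_SKELETON} values, got {arr.size}")
        return cls(arr.reshape(N_KEYPOINTS, 3), overall_score)


@dataclass
class FrameDetections:
    """All detections in one frame; ``detections`` may be empty."""

    frame_index: int
    detections: list[PoseDetection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


_TRAILING_INT = re.compile(r"(\d+)\s*$")


def frame_index_from_image_id(image_id: str) -> int:
    """Extract the frame index from an image name such as ``"img_00042.png"``.

    The extension is stripped and the trailing integer of the stem parsed;
    a stem without a trailing integer is a format error.
    """
    stem = Path(str(image_id)).stem
    m = _TRAILING_INT.search(stem)
    if m is None:
        raise FormatError(f"image id {image_id!r} has no trailing frame number")
    return int(m.group(1))


def parse_pose_results(source: Union[PathLike, IO[str], str]) -> list[FrameDetections]:
    """Parse a pose-estimation result file into per-frame detection groups.

    Accepts a path, an open text stream, or a JSON string.  Records are
    grouped by frame and frames returned in ascending ``frame_index`` order;
    within a frame, detections keep file order (the tie-break order used by
    person-of-interest selection).  Frames with no record do not appear.
    """
    if hasattr(source, "read"):
        records = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith(("[", "{")):
            records = json.loads(text)
        else:
            with open(source, "r") as fh:
                records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError("pose result file must be a JSON list of records")

    frames: dict[int, FrameDetections] = {}
    for rec in records:
        try:
            image_id = rec["image_id"]
            kp = rec["keypoints"]
            score = float(rec["score"])
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed pose record: {rec!r}") from exc
        idx = frame_index_from_image_id(image_id)
        if len(kp) != FEATURES_PER_SKELETON:
            raise FormatError(
                f"frame {idx}: keypoint list has {len(kp)} values, "
                f"expected {FEATURES_PER_SKELETON}"
            )
        if not np.isfinite(score):
            raise FormatError(f"frame {idx}: non-numeric score")
        det = PoseDetection.from_flat(kp, score)
        frames.setdefault(idx, FrameDetections(idx)).detections.append(det)
    return [frames[i] for i in sorted(frames)]


def read_frame_labels(
    source: Union[PathLike, IO[str]],
    vocabulary: Iterable[int] = DEFAULT_VOCABULARY,
) -> dict[int, int]:
    """Read a ``frame,label`` CSV into a frame-index -> activity-id mapping.

    Duplicate frame rows and labels outside the declared vocabulary are
    rejected.
    """
    df = pd.read_csv(source)
    for col in ("frame", "label"):
        if col not in df.columns:
            raise FormatError(f"label table missing column {col!r}")
    vocab = set(int(v) for v in vocabulary)
    table: dict[int, int] = {}
    for frame, label in zip(df["frame"].astype(int), df["label"].astype(int)):
        if frame < 0:
            raise FormatError(f"negative frame index {frame}")
        if frame in table:
            raise FormatError(f"duplicate label row for frame {frame}")
        if label not in vocab:
            raise FormatError(f"frame {frame}: label {label} outside vocabulary")
        table[frame] = label
    return table


def write_frame_labels(table: Mapping[int, int], sink: Union[PathLike, IO[str]]) -> None:
    """Write a frame-label mapping as a ``frame,label`` CSV, sorted by frame."""
    frames = sorted(table)
    df = pd.DataFrame({"frame": frames, "label": [table[f] for f in frames]})
    df.to_csv(sink, index=False)


def write_feature_table(matrix, sink: Union[PathLike, IO[str]]) -> None:
    """Write a feature matrix as CSV ``label,f0,...,f{F-1}``.

    Values are written with 17 significant digits so that float64 round-trips
    exactly through the text representation.
    """
    width = matrix.width
    df = pd.DataFrame(matrix.values, columns=[f"f{i}" for i in range(width)])
    df.insert(0, "label", matrix.labels)
    df.to_csv(sink, index=False, float_format="%.17g")


def read_feature_table(source: Union[PathLike, IO[str]]):
    """Read a feature-table CSV back into a :class:`FeatureMatrix`.

    Ragged rows (a row narrower or wider than the header) are format errors.
    """
    from skelwin.windowing import FeatureMatrix  # cycle: windowing owns the type

    try:
        df = pd.read_csv(source, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged feature table: {exc}") from exc
    if len(df.columns) == 0 or df.columns[0] != "label":
        raise FormatError("feature table must start with a 'label' column")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(values).any():
        rows = np.nonzero(np.isnan(values).any(axis=1))[0]
        raise FormatError(f"ragged feature table: short row(s) at index {rows.tolist()}")
    labels = df["label"].to_numpy(dtype=int)
    return FeatureMatrix(values=values, labels=labels)
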