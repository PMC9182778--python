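"""Reduce multi-person frames to one person of interest per frame.

Recordings often show bystanders in addition to the volunteer performing
the activity.  Per frame, the detection with the highest overall score is
kept and all others discarded; frames with no detection are dropped.  The
result is a clean per-video track: one skeleton and one label per retained
frame, treated as temporally consecutive for windowing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from skelwin.skeleton_io import (
    FEATURES_PER_SKELETON,
    FormatError,
    FrameDetections,
    PathLike,
    PoseDetection,
)

logger = logging.getLogger(__name__)


@dataclass
class VideoPoseTrack:
    """One video reduced to one skeleton per retained frame.

    ``features`` is (n_frames, 51): row i is the flat view of the skeleton
    kept in the i-th retained frame.  ``frame_indices`` keeps the original
    frame numbers for traceability only; windowing treats the retained
    frames as consecutive.
    """

    video_id: str
    fps: int
    frame_indices: np.ndarray
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.features = np.asarray(self.features, dtype=float).reshape(
            -1, FEATURES_PER_SKELETON
        )
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.frame_indices)
        if self.features.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("frame_indices, features and labels must have equal length")
        if n > 1 and not np.all(np.diff(self.frame_indices) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.fps < 1:
            raise ValueError("fps must be a positive integer")

    @property
    def n_frames(self) -> int:
        return int(self.features.shape[0])


def select_person_of_interest(frame: FrameDetections) -> Optional[PoseDetection]:
    """Return the detection with the highest overall score, or None if empty.

    Ties are broken by file order: the earlier record wins.
    """
    if not frame.detections:
        return None
    best = frame.detections[0]
    for det in frame.detections[1:]:
        if det.overall_score > best.overall_score:
            best = det
    return best


def build_track(
    frames: Sequence[FrameDetections],
    labels: Mapping[int, int],
    fps: int,
    video_id: str = "video",
) -> VideoPoseTrack:
    """Build a clean track: drop empty frames, keep the best skeleton per frame.

    Every non-empty frame must have a label in ``labels``; a missing label is
    an error naming the frame.
    """
    kept_idx: list[int] = []
    kept_feat: list[np.ndarray] = []
    kept_lab: list[int] = []
    for frame in sorted(frames, key=lambda f: f.frame_index):
        det = select_person_of_interest(frame)
        if det is None:
            continue
        if frame.frame_index not in labels:
            raise FormatError(f"frame {frame.frame_index} has a detection but no label")
        kept_idx.append(frame.frame_index)
        kept_feat.append(det.flat)
        kept_lab.append(labels[frame.frame_index])
    features = (
        np.vstack(kept_feat) if kept_feat else np.empty((0, FEATURES_PER_SKELETON))
    )
    return VideoPoseTrack(
        video_id=video_id,
        fps=int(fps),
        frame_indices=np.asarray(kept_idx, dtype=int),
        features=features,
        labels=np.asarray(kept_lab, dtype=int),
    )


def write_track(track: VideoPoseTrack, sink: Union[PathLike, IO[str]]) -> None:
    """Write a track as CSV ``frame,label,f0,...,f50``."""
    df = pd.DataFrame(
        track.features, columns=[f"f{i}" for i in range(FEATURES_PER_SKELETON)]
    )
    df.insert(0, "label", track.labels)
    df.insert(0, "frame", track.frame_indices)
    df.to_csv(sink, index=False, float_format="%.17g")


def read_track(
    source: Union[PathLike, IO[str]], fps: int, video_id: str = "video"
) -> VideoPoseTrack:
    """Read a track CSV written by :func:`write_track`."""
    df = pd.read_csv(source, float_precision="round_trip")
    expected = ["frame", "label"] + [f"f{i}" for i in range(FEATURES_PER_SKELETON)]
    if list(df.columns) != expected:
        raise FormatError("track file does not have the frame,label,f0..f50 layout")
    return VideoPoseTrack(
        video_id=video_id,
        fps=int(fps),
        frame_indices=df["frame"].to_numpy(dtype=int),
        features=df.iloc[:, 2:].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
    )
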