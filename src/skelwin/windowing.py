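"""Sliding windows over skeleton tracks and window feature vectors.

A window spans ``SWL = fps x W`` consecutive frames and advances one frame
at a time, so a video of n frames yields ``SWm = n - SWL + 1`` windows.
From each window, ``S`` evenly spaced skeletons (always including the first
and last frame) are selected and their 51-value flat views concatenated in
temporal order into a feature vector of length ``F = 51 x S``.  Each window
is labeled with the statistical mode of its frame labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from skelwin.skeleton_io import FEATURES_PER_SKELETON
from skelwin.preprocess import VideoPoseTrack

logger = logging.getLogger(__name__)


def compute_swl(fps: int, window_seconds: float) -> int:
    """Window length in frames: fps x duration, rounded half-up, minimum 2."""
    if fps < 1:
        raise ValueError("fps must be >= 1")
    if window_seconds <= 0:
        raise ValueError("window duration must be positive")
    swl = int(math.floor(fps * window_seconds + 0.5))
    return max(swl, 2)


def count_windows(n_frames: int, swl: int) -> int:
    """Number of stride-1 windows: n - SWL + 1, or 0 for too-short videos."""
    if swl < 2:
        raise ValueError("SWL must be >= 2")
    if n_frames < swl:
        return 0
    return n_frames - swl + 1


def select_offsets(swl: int, n_skeletons: int) -> np.ndarray:
    """Frame offsets of the S selected skeletons within an SWL-frame window.

    offsets[k] = floor(k / (S-1) * (SWL-1)); the first offset is 0 and the
    last SWL-1, so the window endpoints are always included.  For S = 3 this
    selects the first, middle and last frame.
    """
    if not 2 <= n_skeletons <= swl:
        raise ValueError(f"S must satisfy 2 <= S <= SWL, got S={n_skeletons}, SWL={swl}")
    k = np.arange(n_skeletons, dtype=int)
    offsets = (k * (swl - 1)) // (n_skeletons - 1)
    return offsets


@dataclass(frozen=True)
class WindowSpec:
    """The (W, fps, SWL, S, offsets, F) configuration governing windowing."""

    window_seconds: float
    fps: int
    n_skeletons: int
    swl: int = field(init=False)
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        swl = compute_swl(self.fps, self.window_seconds)
        offsets = select_offsets(swl, self.n_skeletons)
        offsets.setflags(write=False)
        object.__setattr__(self, "swl", swl)
        object.__setattr__(self, "offsets", offsets)

    @property
    def n_features(self) -> int:
        """Feature-vector length F = 51 x S."""
        return FEATURES_PER_SKELETON * self.n_skeletons


@dataclass
class FeatureMatrix:
    """Stacked window feature vectors: one row and one label per window."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("one label per row required")

    @property
    def n_windows(self) -> int:
        return int(self.values.shape[0])

    @property
    def width(self) -> int:
        return int(self.values.shape[1])

    @staticmethod
    def concat(matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Pool windows across videos (rows stacked in the given order)."""
        widths = {m.width for m in matrices}
        if len(widths) > 1:
            raise ValueError(f"cannot pool matrices of different widths: {widths}")
        return FeatureMatrix(
            values=np.vstack([m.values for m in matrices]),
            labels=np.concatenate([m.labels for m in matrices]),
        )


def window_label(labels: Sequence[int]) -> int:
    """Statistical mode of a window's frame labels; ties -> smallest label id."""
    arr = np.asarray(labels, dtype=int)
    if arr.size == 0:
        raise ValueError("cannot take the mode of an empty label window")
    if np.any(arr < 0):
        raise ValueError("labels must be non-negative")
    # bincount argmax returns the smallest id among tied counts
    return int(np.argmax(np.bincount(arr)))


def build_feature_matrix(track: VideoPoseTrack, spec: WindowSpec) -> FeatureMatrix:
    """Window a track: row i concatenates the skeletons at i + spec.offsets.

    Row i's label is the mode of the frame labels i ... i+SWL-1.  A track
    shorter than SWL yields an empty matrix with a warning (the video is
    skipped, its duration being below the window size).
    """
    if track.fps != spec.fps:
        raise ValueError(f"track fps {track.fps} does not match spec fps {spec.fps}")
    n_win = count_windows(track.n_frames, spec.swl)
    if n_win == 0:
        logger.warning(
            "video %s has %d frames < SWL=%d; no windows produced",
            track.video_id,
            track.n_frames,
            spec.swl,
        )
        return FeatureMatrix(
            values=np.empty((0, spec.n_features)), labels=np.empty(0, dtype=int)
        )
    starts = np.arange(n_win)
    # gather: (n_win, S, 51) -> (n_win, F)
    values = track.features[starts[:, None] + spec.offsets[None, :]].reshape(
        n_win, spec.n_features
    )
    labels = np.array(
        [window_label(track.labels[i : i + spec.swl]) for i in starts], dtype=int
    )
    return FeatureMatrix(values=values, labels=labels)


def frame_feature_matrix(track: VideoPoseTrack) -> FeatureMatrix:
    """Frame-by-frame baseline: each frame's 51 features as one row.

    This is the single-skeleton (S=1, no window) predecessor representation
    the windowed features are compared against.
    """
    return FeatureMatrix(values=track.features.copy(), labels=track.labels.copy())
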