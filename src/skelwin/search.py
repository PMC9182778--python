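"""Exhaustive search over window duration W and skeleton count S.

The objective is cross-validated recall: for every candidate (W, S) with
S = 2 ... SWL, all tracks are windowed, windows pooled across videos, and
the repeated-split protocol run; the candidate with the highest mean recall
wins.  Ties are broken toward fewer features (smaller F), then smaller W,
preferring the cheapest equally good representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd

from skelwin.preprocess import VideoPoseTrack
from skelwin.models_eval import MODEL_IDS, ProtocolConfig, run_protocol
from skelwin.skeleton_io import PathLike
from skelwin.windowing import FeatureMatrix, WindowSpec, build_feature_matrix, compute_swl

logger = logging.getLogger(__name__)

DEFAULT_W_GRID = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class SearchConfig:
    """Grid and protocol configuration for the exhaustive (W, S) search."""

    w_grid: tuple[float, ...] = DEFAULT_W_GRID
    max_window_seconds: Optional[float] = None
    model: str = "rf"
    rounds: int = 10
    seed: int = 0
    task: str = "multiclass"

    def __post_init__(self) -> None:
        if not self.w_grid:
            raise ValueError("window-duration grid must be non-empty")
        if any(w <= 0 for w in self.w_grid):
            raise ValueError("window durations must be positive")
        if self.model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class SearchResult:
    """Full candidate table plus the argmax-recall best candidate."""

    table: pd.DataFrame
    best: dict

    def to_csv(self, sink: Union[PathLike, IO[str]]) -> None:
        """Write the candidate table; 17 significant digits keep it byte-stable."""
        self.table.to_csv(sink, index=False, float_format="%.17g")


def enumerate_candidates(fps: int, config: SearchConfig) -> list[tuple[float, int]]:
    """All (W, S) candidates: for each W, S runs from 2 to SWL = fps x W."""
    if fps < 1:
        raise ValueError("fps must be >= 1")
    candidates: list[tuple[float, int]] = []
    for w in sorted(config.w_grid):
        if config.max_window_seconds is not None and w > config.max_window_seconds:
            raise ValueError(
                f"window duration {w} s exceeds the maximum admissible "
                f"{config.max_window_seconds} s"
            )
        swl = compute_swl(fps, w)
        candidates.extend((w, s) for s in range(2, swl + 1))
    return candidates


def exhaustive_search(
    tracks: Sequence[VideoPoseTrack], config: SearchConfig
) -> SearchResult:
    """Evaluate every (W, S) candidate and return the recall-maximizing one.

    Tracks shorter than a candidate's SWL are skipped for that candidate with
    a warning.  The recall maximized is the one reported by the protocol:
    positive-class recall for the binary task, macro recall for multiclass.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    fps_set = {t.fps for t in tracks}
    if len(fps_set) > 1:
        raise ValueError(f"tracks disagree on fps: {sorted(fps_set)}")
    fps = fps_set.pop()
    candidates = enumerate_candidates(fps, config)
    if not candidates:
        raise ValueError("empty candidate set")

    rows = []
    for w, s in candidates:
        spec = WindowSpec(window_seconds=w, fps=fps, n_skeletons=s)
        parts = []
        for track in tracks:
            if track.n_frames < spec.swl:
                logger.warning(
                    "video %s shorter than SWL=%d at W=%g s; skipped",
                    track.video_id,
                    spec.swl,
                    w,
                )
                continue
            parts.append(build_feature_matrix(track, spec))
        if not parts:
            raise ValueError(f"every track is shorter than SWL at W={w} s")
        pooled = FeatureMatrix.concat(parts)
        proto = ProtocolConfig(model=config.model, rounds=config.rounds, seed=config.seed)
        report = run_protocol(pooled, proto, task=config.task)
        rows.append(
            {
                "W": w,
                "S": s,
                "F": spec.n_features,
                "n_windows": pooled.n_windows,
                "mean_recall": report.mean("recall"),
                "sd_recall": report.sd("recall"),
            }
        )
        logger.info(
            "candidate W=%g s S=%d F=%d: recall %.2f +- %.2f",
            w, s, spec.n_features, rows[-1]["mean_recall"], rows[-1]["sd_recall"],
        )

    table = pd.DataFrame(rows, columns=["W", "S", "F", "n_windows", "mean_recall", "sd_recall"])
    order = table.sort_values(
        by=["mean_recall", "F", "W"], ascending=[False, True, True], kind="mergesort"
    )
    best = order.iloc[0].to_dict()
    best["S"] = int(best["S"])
    best["F"] = int(best["F"])
    best["n_windows"] = int(best["n_windows"])
    return SearchResult(table=table, best=best)
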