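"""Simulate pose-estimation output and reduce it to clean skeleton tracks.

Generates two short synthetic videos (a sideways fall and a person lying
down), writes them in the pose-result/label file conventions, then parses
the files back and keeps one skeleton per frame (highest detection score;
empty frames dropped).
"""

import tempfile
from pathlib import Path

from skelwin import SimConfig, build_track, parse_pose_results, read_frame_labels
from skelwin.synthetic import simulate_dataset

config = SimConfig(
    scripts=(((5, 4.0),), ((11, 4.0),)),  # (activity id, seconds) per video
    distractor_prob=0.3,
    empty_frame_prob=0.05,
    seed=7,
)

with tempfile.TemporaryDirectory() as tmp:
    pairs = simulate_dataset(config, Path(tmp))
    for pose_path, label_path in pairs:
        frames = parse_pose_results(pose_path)
        labels = read_frame_labels(label_path)
        n_people = sum(len(f.detections) for f in frames)
        track = build_track(frames, labels, fps=config.fps, video_id=pose_path.stem)
        print(
            f"{pose_path.name}: {len(frames)} non-empty frames, "
            f"{n_people} detections -> track of {track.n_frames} skeletons, "
            f"activity {track.labels[0]}"
        )

# Each video is 4 s at 18 fps = 72 ticks; ~5% of frames are empty and are
# dropped, and frames with a bystander are reduced to the volunteer's
# skeleton, so each track holds ~68 rows of 51 features (17 joints x x,y,s).
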