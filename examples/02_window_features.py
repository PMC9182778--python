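"""Turn a skeleton track into sliding-window feature vectors.

A 2-second window at 18 fps spans SWL = 36 frames; selecting S = 3 evenly
spaced skeletons (first, middle, last frame) concatenates 3 x 51 = 153
features per window.  The window label is the mode of its 36 frame labels.
"""

from skelwin import WindowSpec, build_feature_matrix, compute_swl, count_windows
from skelwin.synthetic import confusable_pair_config, simulate_tracks

track = simulate_tracks(confusable_pair_config(n_videos_per_class=1, seed=3))[0]
spec = WindowSpec(window_seconds=2.0, fps=18, n_skeletons=3)

print(f"track: {track.n_frames} frames at {track.fps} fps")
print(f"SWL = {compute_swl(track.fps, 2.0)} frames, offsets = {spec.offsets.tolist()}")
print(f"expected windows: {count_windows(track.n_frames, spec.swl)}")

matrix = build_feature_matrix(track, spec)
print(f"feature matrix: {matrix.n_windows} windows x {matrix.width} features")
print(f"window labels: all equal {matrix.labels[0]} (single-activity video)")

# With ~70 retained frames the video yields ~35 windows; every row holds the
# flat (x, y, score) views of the skeletons at window offsets 0, 17 and 35,
# so column block k is exactly frame (window_start + offsets[k]).
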