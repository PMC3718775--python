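"""Robust piecewise-linear segmentation of a noisy gaze recording.

Simulates 20 s of future-path tracking gaze at 60 Hz (Gaussian noise
0.5 deg per axis, tracker glitches at 0.5/s), runs the
penalized-likelihood segmentation, and compares recovered slow-phase
slopes and outliers against the generator's ground truth.
"""

import numpy as np

from okncurve import (
    RoadModel,
    SyntheticConfig,
    classify_segments,
    generate_cornering_telemetry,
    per_sample_velocity,
    segment_gaze,
    simulate_gaze,
)

road = RoadModel()
tel = generate_cornering_telemetry(road, 11.86, duration=20.0)
gaze, truth = simulate_gaze(tel, road, SyntheticConfig(seed=0))

result = classify_segments(segment_gaze(gaze))
n_sp = sum(s.label == "SP" for s in result.segments)
print(f"{len(gaze)} samples -> {len(result.segments)} segments "
      f"({n_sp} slow phases), {len(result.outlier_idx)} outliers flagged "
      f"(truth: {truth.n_segments} episodes, {len(truth.outlier_idx)} outliers)")
print(f"penalized log-likelihood of the partition: {result.score:.1f}")

hit = len(set(result.outlier_idx) & set(truth.outlier_idx))
print(f"outliers recovered: {hit}/{len(truth.outlier_idx)}")

vel = per_sample_velocity(result, gaze)
true_vel = np.empty(len(gaze))
for (s, e), sl in zip(truth.spans(len(gaze)), truth.slopes_h):
    true_vel[s:e] = sl
ok = vel["ok"].to_numpy()
err = np.abs(vel["vel_h"].to_numpy() - true_vel)[ok]
print(f"per-sample |horizontal slope error|: median {np.median(err):.2f} deg/s")

omega = tel["yaw"].iloc[0]
sp_slopes = [s.slope_h for s in result.segments if s.label == "SP"]
print(f"median recovered SP horizontal velocity: {np.median(sp_slopes):+.2f} "
      f"deg/s vs -omega/2 = {-omega / 2:+.2f} deg/s")
print("\nSlow phases drift opposite the curve at half the yaw rate — the")
print("optokinetic signature of tracking points on the future path.")
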