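"""Per-frame estimates of a walking subject, and their robust aggregation.

Trains a small model on walking sequences of a training population, then
estimates one new subject's weight in every frame of their walk toward the
camera.  Single frames scatter (posture and distance change continuously);
the mean-pairwise-distance clustering keeps the tightest 20 % of the
estimates and averages them into one final value.
"""

import numpy as np

from weightsense import (
    NetworkConfig,
    SceneSpec,
    SyntheticSubject,
    predict,
    render_walk,
    stream_estimate,
    train,
)
from weightsense.features import FEATURE_NAMES
from weightsense.pipeline import PipelineConfig, build_feature_table, extract_frame_features, feature_matrix
from weightsense.stream import mean_pairwise_distance, select_core
from weightsense.synthetic import render_reference

train_cfg = PipelineConfig(mode="walking", n_subjects=12, frames_per_subject=6, seed=5)
train_cfg.scene.thermal = False
table = build_feature_table(train_cfg)
x, names = feature_matrix(table)
model = train(x, table["ground_truth_kg"].to_numpy(), NetworkConfig(seed=5),
              person_ids=table["person_id"].to_numpy(), feature_names=names)

subject = SyntheticSubject(height_m=1.78, girth=1.05, gender="male", person_id=99)
spec = SceneSpec(mode="walking", thermal=False)
reference = render_reference(spec, seed=train_cfg.seed + 500_009)

estimates = []
for cloud, _labels in render_walk(subject, spec, 15, seed=123):
    fv = extract_frame_features(cloud, "walking", train_cfg.segmentation,
                                spec.intrinsics, reference=reference, gender="male")
    row = np.array([fv.values[FEATURE_NAMES.index(n)] for n in names])
    estimates.append(predict(model, row))
estimates = np.asarray(estimates)

d_bar = mean_pairwise_distance(estimates)
core = select_core(estimates, d_bar, 0.2)
final = stream_estimate(estimates, 0.2)

print(f"ground truth: {subject.ground_truth_kg:.1f} kg")
print("per-frame estimates (kg):", np.round(estimates, 1))
print("kept frames (tightest 20 %):", [int(i) for i in core], "->", np.round(estimates[core], 1))
print(f"stream estimate: {final:.1f} kg "
      f"({100 * abs(subject.ground_truth_kg - final) / subject.ground_truth_kg:.1f} % off)")
print("\nThe kept frames are the mutually closest estimates; averaging them "
      "suppresses the outlier frames where segmentation or posture degraded "
      "the single-frame estimate.")
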