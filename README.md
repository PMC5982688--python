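# weightsense

Contact-less body-weight estimation from RGB-D(-T) point clouds of lying,
standing and walking people.

Emergency stroke patients are dosed with rtPA at 0.9 mg per kg of body
weight (±10 % is the accepted tolerance), but they usually cannot stand on
a scale and physicians' visual guesses miss the band for roughly every
third patient.  `weightsense` implements a camera-based alternative: a
depth (and optionally thermal) camera observes the patient, the person is
segmented from the scene, a compact shape descriptor is computed, and a
small neural network returns the weight in kilograms.  The same feature set
works for a patient on a stretcher, a person standing in front of the
camera, and — with a robust per-frame aggregation — a person walking
toward it.

## Method

The scene cloud `P` is split into person `Pp` and environment `PE`
(`P = Pp + PE`): thermal thresholding + RANSAC stretcher-plane removal in
the clinical setting, background subtraction + floor removal for
standing/walking, largest Euclidean component in both.  From `Pp` a
19-feature descriptor is computed:

- frontal-surface **volume** `v` (lying only) and mesh **surface** `s`,
  point count `|Pp|`, scene density `|Pp|/|P|`;
- eigenvalues `λ1 ≥ λ2 ≥ λ3` of the scatter matrix
  `S = Σ_j (p_j − p̄)(p_j − p̄)ᵀ` and the rigid-invariant shape ratios
  **sphericity** `λ3/Σλ`, **flatness** `2(λ2−λ3)/Σλ`,
  **linearity** `(λ1−λ2)/Σλ`;
- statistical moments of the centroid distances;
- silhouette contour and convex-hull perimeter/area (pixels);
- distance to the person and (given) gender.

A three-layer feed-forward network (tanh hidden layer, linear output neuron
in kg) is trained by resilient propagation (iRPROP⁻) with weight decay and
validation-based early stopping, on a 70/30 subject-level split.  For a
walking sequence with per-frame estimates `w_1..w_N`, each frame's mean
absolute distance to all other estimates is computed
(`d̄_i = 1/(N−1) Σ_{j≠i} |w_i − w_j|`), the tightest 20 % of frames are
kept, and their mean is the final estimate — single frames can be off by
more than 30 %, the cluster of mutually-consistent frames is not.

Everything runs on synthetic scenes out of the box: a parametric humanoid
(ten disjoint ellipsoids, analytic volume × 985 kg/m³ = exact ground-truth
weight) is ray-cast into organized depth(-thermal) clouds with sensor
noise, so the whole pipeline is testable without downloads.  Real
recordings in the PCD format with the `GENDER_WEIGHT_PERSON_FRAME.pcd`
naming convention are read directly.

## Worked example

```sh
python examples/lying_experiment.py
```

simulates 60 patients on a stretcher, trains on 42 and evaluates on 18:

```
mode: lying, 42 training / 18 test subjects

  relative_error_min_pct       -13.17
  relative_error_max_pct         4.72
  relative_error_mean_pct       -3.04
  relative_error_sd_pct          4.70
  in_range_5_pct                72.22
  in_range_10_pct               88.89
  in_range_20_pct              100.00
  mae_kg                         3.01
  mse_kg2                       13.04
```

The mean relative error near zero means no systematic bias;
`in_range_10_pct` is the share of held-out subjects whose estimate is
inside the ±10 % dosing band; MAE is the mean absolute error in kg.
`examples/extract_features_from_pcd.py` prints the full descriptor of one
segmented frame, and `examples/walking_stream_aggregation.py` shows the
per-frame scatter of a walking subject collapsing into one aggregate.

There is also a thin CLI:

```sh
weightsense simulate --mode lying --n 10 --seed 7 --out fixtures/
weightsense extract --mode lying --out features.csv fixtures/*.pcd
weightsense train --features features.csv --out model.json
weightsense run --mode standing --n 100 --seed 1 --out report.json
```

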