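# Methods

`weightsense` estimates a person's body weight from a single depth(-thermal)
point cloud, or from a stream of them, without any contact.  This note
documents the models, the parameters that matter, the synthetic study
population the tests run on, and the numerical choices made where the design
was genuinely open.

## Problem and pipeline

In stroke care the thrombolytic rtPA is dosed at 0.9 mg per kg of body
weight, with ±10 % the commonly cited tolerance — yet emergency patients can
rarely be weighed.  The pipeline estimates weight from an overhead or
frontal RGB-D(-T) view in four stages:

1. **Segmentation** splits the scene cloud `P` into person `Pp` and
   environment `PE` with `P = Pp + PE` over valid points.
2. **Feature extraction** reduces `Pp` to a 19-element descriptor.
3. **Regression** maps the descriptor to kilograms with a three-layer
   feed-forward network trained by resilient propagation.
4. **Stream aggregation** (walking subjects only) fuses per-frame estimates
   into one robust value.

## Segmentation

*Lying (clinical) recipe* — the scene is cropped to the floor-marker region
of interest; the stretcher surface is found by RANSAC (500 three-point
hypotheses, 1.5 cm inlier tolerance, fixed seed, ties by lower iteration
index, no refit — the winning hypothesis is returned verbatim so runs are
bit-reproducible).  The plane is fitted on the cropped *scene*, not on the
person candidates: a lying torso is itself nearly planar, and fitting after
thermal selection would lock onto the patient instead of the stretcher.
When a thermal channel is present, person candidates are points at or above
30 °C (skin is 33–36 °C, room surfaces 20–25 °C); without one, the
candidates are the non-plane points, which is the documented weaker path
(bystanders can survive it).  Stretcher inliers are removed from the
candidates, the largest Euclidean component (5 cm linkage) is kept, and a
morphological opening (disc radius 2 px) on the pixel-grid mask removes
speckle.

*Standing/walking recipe* — background subtraction against a person-free
reference frame (5 cm change threshold, a few sigma above depth noise at
2–4 m), removal of the reference scene's dominant plane (the floor in a
walking lane; fitted on the reference so it can never lock onto the
person), a statistical outlier filter, then the largest component.

The outlier filter drops points whose mean distance to their 20 nearest
neighbors exceeds the global mean + 6 sd of that statistic.  The gate is
deliberately loose: its target is flying-pixel/jumping-edge artifacts that
sit decimeters off the surface, whereas silhouette-edge points legitimately
have 2–3× the median neighbor spacing (grazing incidence) and must not be
shaved off.  A small relative tolerance on the cutoff keeps float jitter
from splitting an exactly-uniform cloud.

## Feature descriptor

For the person's points `p_j` with centroid `p̄`:

| group | features |
|---|---|
| geometry | frontal volume `v` (m³, lying only), mesh surface `s` (m²), `|Pp|`, density `|Pp|/|P|` |
| eigen | `λ1 ≥ λ2 ≥ λ3` of the scatter matrix `S = Σ (p_j−p̄)(p_j−p̄)ᵀ`; sphericity `λ3/Σλ`, flatness `2(λ2−λ3)/Σλ`, linearity `(λ1−λ2)/Σλ` |
| moments | compactness `√(1/n Σ‖p_j−p̄‖²)` (RMS centroid distance, m), the summed centroid distance `Σ‖p_j−p̄‖`, and a fourth moment `1/n Σ‖p_j−p̄‖⁴` divided by flatness |
| silhouette | contour perimeter/area and convex-hull perimeter/area of the projected mask, in pixels |
| distance, gender | centroid distance to the sensor (m); gender as a given 0/1 input, never inferred |

Numerical conventions that had to be fixed:

- The scatter matrix is the **unnormalized sum** (eigenvalues at the 10³ m²
  scale for ~10⁴ points on a standing adult); all ratio features are
  unaffected by this choice.  Normalized eigenvalues are available behind a
  switch; the ratios already carry the normalized information.
- The summed centroid distance is kept under its historical label
  "kurtosis"; dividing the fourth moment by flatness is dimensionally odd
  but retained as the descriptor's established form (it is flagged
  unavailable when flatness is zero).
- The frontal mesh triangulates every 2×2 pixel quad whose four points are
  valid and whose depth range stays below a 5 cm jump threshold, so
  jumping-edge artifacts at silhouettes are not bridged.  Volume is the sum
  of prisms: triangle area projected onto the stretcher plane × mean vertex
  distance to the plane; plane orientation is auto-resolved and the result
  clamped at ≥ 0.  On analytic solids (box patch, half-cylinder) at 5 mm
  sampling the error is under 2 %.
- Silhouette convention: largest 8-connected blob; outer border by
  Moore-neighbor tracing; contour length is the polygon length through
  border pixel centers (a filled 10×10 square gives 36 px), contour area
  the blob's pixel count (100 px²); hull length is the convex-hull polygon
  of the border pixels, hull area the pixel count of the filled hull, so
  `hull_length ≤ contour_length` and `hull_area ≥ contour_area` always
  hold and both pairs coincide for convex silhouettes.
- Distance to the person is the centroid distance (nearest-point available
  via an argument); the quantity was never formally defined upstream.

A known discrepancy is documented rather than repaired: the published
worked-example table's sphericity cells do not reconcile with `λ3/Σλ`
applied to the printed eigenvalues (scene 1: printed 4.1×10⁻² vs computed
1.4×10⁻²), and one linearity cell appears to carry an exponent typo.  The
formulas are implemented as printed in the feature table; the flatness and
linearity cells that do reconcile are regression-tested at printed
precision, the boundary cases within ±0.015.

## Weight regression

A three-layer network: inputs (the available features, standardized on the
training rows) → one tanh hidden layer (default 16 units) → one linear
output neuron, the weight in kg (internally standardized).  Training is
full-batch iRPROP⁻ (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δ ∈ [10⁻⁶, 50] — the
standard published constants) on squared error with L2 weight decay
(λ = 10⁻⁴ default).  15 % of the training subjects are held out as a
validation set; training stops after 50 epochs without validation
improvement (2000 epochs cap) and the best-validation weights are returned.
All randomness flows from one seed; identical seeds give identical weights.

Data are split 70/30 at **subject** granularity, so no person contributes
frames to both sides.  Features unavailable in a mode (volume for standing
subjects — there is no reference surface behind the back) are masked out of
the model rather than imputed.

Evaluation: relative error `ε_i = (truth_i − estimate_i)/truth_i` (positive
= underestimate), MAE `= 1/N Σ|e_i|` (kg), MSE `= 1/N Σ e_i²` (kg²), and
the share of subjects within ±5/10/20 % — ±10 % being the dosing band.

## Stream aggregation

For a walking sequence's estimates `w_1..w_N`: compute each frame's mean
absolute distance to all other estimates, keep the `max(1, round(0.2·N))`
frames with the smallest distances (ties to the earlier frame), and return
the mean of the kept estimates.  The upstream definition prints divisor `N`
over the `N−1` summed terms; since ranking is scale-invariant the aggregate
is identical under either convention — the default here is `N−1` (the true
mean), with `divisor="N"` available.  The estimate always lies inside
`[min w, max w]`, and with fewer than `0.2·N` adversarial outliers the
inlier cluster wins.

## Synthetic study population

Real recordings cannot ship with the package, so every stage is exercised
on a generator that emulates the three recording settings.

*Body model.*  A humanoid of ten axis-aligned ellipsoids (head, torso,
pelvis, two full arms, thighs, shanks) in a body frame.  Parts are pairwise
**disjoint** — so the ground-truth volume is exactly the sum of ellipsoid
volumes, `V = V₀·s³·γ²` for height scale `s` and transverse girth `γ` — yet
the rendered surface stays Euclidean-connected at the segmentation's 5 cm
linkage radius: the head–torso–pelvis chain and the knee/ankle joints touch
pole-to-pole on a shared axis (junctions that are robust at any pixel
pitch), the wide pelvis hovers directly over the thigh axes with real
frontal depth, and the arms run along the torso flank at ~1 cm clearance.
Posture (arms raised toward the chest, crossed-arm variant, leg stance,
walking swing and sway) only translates parts within capped offsets, so
volume is posture-independent.  Ground-truth weight is `985 kg/m³ × V`
(near-water soft tissue) — an exact deterministic label.

*Population.*  Height is log-normal (median 1.78 m male / 1.66 m female,
4 % log-sd), girth log-normal (8 % log-sd) with a fixed calibration factor
1.05 that absorbs the ellipsoid union's underestimate of real body girth;
draws outside a 45–140 kg plausibility band are rejected.  For n ≥ 200 the
weight distribution lands at mean ≈ 79 kg, sd ≈ 17 kg, matching the mixed
adult cohorts the method was built for.

*Scenes.*  Ray casting through a pinhole model (256×192, ~58° field of
view) against the body, a stretcher rectangle + floor (lying, camera
overhead at 2 m) or a floor + back wall (standing/walking, camera at
1.5 m).  Gaussian noise (default σ = 3 mm) is added along each ray; the
thermal channel is 36 °C on skin, 22 °C elsewhere; per-point labels are
returned out of band.  Walking sequences advance from 3.4 m to 2.2 m with
arm/leg swing, frame-to-frame posture jitter and ±4 cm lateral sway —
without that variation, per-frame estimates are unrealistically tight,
whereas real walking sequences scatter strongly frame to frame (which is
the reason the aggregation stage exists).

*What the generator does not emulate*: clothing, self-occluding limbs,
sensor-specific noise fields (structured-light shadows, ToF multipath),
cluttered multi-person scenes, children.  Passing tests therefore
demonstrate the pipeline's internal correctness and its behavior under
controlled geometry/noise, not clinical-grade accuracy on real patients.

## Experiment protocols in the test suite

- *Lying and standing*: 300 subjects, one frame each, 70/30 subject split,
  lying keeps the volume feature, standing masks it.  Problem sizes were
  chosen so a full run fits comfortably in a routine test session.
- *Walking*: the per-frame estimator is trained on walking frames (a
  40-subject background population, 8 frames each, plus one short 6-frame
  enrollment walk per cohort subject), because a model trained at a fixed
  standing distance is out of distribution over the walking lane's distance
  sweep, and because a small walking cohort is realistically known to its
  own model — a subject far outside the training weight range is
  systematically mis-estimated, a documented limitation of the approach.
  The evaluated 20-frame walks are never part of training.

## Known limitations

- The volume feature measures the space between the frontal surface and the
  stretcher plane, an overestimate of true body volume; the network absorbs
  the bias but the feature is not physically calibrated.
- RANSAC returns the best 3-point hypothesis without least-squares
  refinement; at 500 iterations and the noise levels here the normal error
  is well under 0.5°, but pathological point sets could benefit from a
  refit.
- The silhouette features depend on sensor resolution and distance (they
  are deliberately not scale-invariant), so models do not transfer across
  camera geometries without retraining.
- Extrapolation beyond the training weight range saturates; the estimator
  should only be trusted inside the population it was trained on.
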