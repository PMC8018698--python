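# Methods

This note documents the models, numerical choices and limitations behind
`stridehall`: a marker-less stride-analysis pipeline for multi-sensor depth
imaging, validated end to end against a bundled synthetic walking-scene
simulator with exact ground truth.

## Coordinate conventions

All lengths are millimetres, times seconds. The room coordinate system
(RCS) is right-handed with x medial-lateral (ML), y anterior-posterior (AP,
along the walkway), z up; it is built from three floor key points: x̂ from
k2 to k3, ŷ from k2 to k1, ẑ = x̂ × ŷ, and the room transform is the
inverse of the assembled pose matrix. Because measured key points are never
exactly orthogonal, ŷ is re-orthogonalised as ẑ × x̂ by default (the
correction is below chessboard measurement noise); a strict mode surfaces
the orthogonality defect instead of fixing it. Pixels are (row, col),
0-based; projection uses floor() semantics with a 1e-9 epsilon so that
exact-integer coordinates (deproject round trips) do not fall on the floor
discontinuity.

## Depth-image stages

* Working range 200–5000 mm; 0 = no data, 5000 = background sentinel.
* 2x2 non-zero median down-sampling; an even count of valid values takes
  the arithmetic mean of the central two, rounded half-up to integer mm;
  an all-zero block stays 0 (invalid propagates).
* Background model: per-pixel minimum over an empty-scene sequence
  (typically 1000 frames), updated only by values strictly inside
  (200, 5000); never-observed cells keep the sentinel.
* Background subtraction keeps pixels strictly in front of the model;
  binarisation scales [0, 5000] → [0, 255] with real-valued division and
  thresholds at 250 (equivalently depth ≥ 4901.96 mm is background). Zero
  is treated as background, which makes the mask/zero-out step idempotent.
* Connected-component filtering uses 8-connectivity (4-connectivity would
  split thin diagonal leg edges) with a 1000 px area cut-off at the design
  resolution of 424x240.

### Resolution scaling

The two pixel-count constants — the 1000 px component cut-off and the
1000-point cluster minimum — measure how many pixels an adult leg subtends
and therefore scale with image area. `PipelineConfig.scaled_for_resolution`
multiplies both by (rows·cols)/(240·424). The validation study renders at
212x120 (a quarter of the design area, scaling both constants to 250),
which keeps a ten-trial study within a few minutes of CPU time while
preserving the method's geometry.

## Point-cloud filter chain

Order fixed as: statistical outlier removal → moving-least-squares (MLS)
smoothing → voxel down-sampling.

* Outlier removal: mean distance to the k = 100 nearest neighbours;
  points above the global mean + 1 sigma of that statistic are dropped.
  Clouds with N ≤ k pass through with a warning; a zero-variance
  distribution (statistically identical points, e.g. a perfect lattice)
  removes nothing, guarded by a relative epsilon against floating-point
  jitter.
* MLS: each point is projected onto a local quadric fitted to neighbours
  within 30 mm, Gaussian-weighted with bandwidth radius/3 (the radius and
  order are the method's; the weighting is ours). Points with fewer than
  6 neighbours — underdetermined for a quadratic — stay put.
  Neighbourhoods are capped at the 32 nearest points for bounded cost; at
  the study's cloud densities the cap is rarely binding.
* Voxel grid: 5 mm, anchored at the room origin, centroid per occupied
  voxel — deterministic and reproducible under translations by voxel
  multiples.

## Leg segmentation

Points below 700 mm are clustered with a 50 mm Euclidean tolerance
(connected components of the ≤ 50 mm adjacency graph, computed on a k-d
tree). Classification: two clusters each ≥ 1000 points with OBB volume
> 0.75x the average leg volume → two legs; one such cluster within
[0.75, 1.25]x → single leg; one cluster > 2x → two legs merged; anything
else is ignored. The average leg dimensions bootstrap from the first 40
per-leg observations of two-cluster frames using the point-count rule only
(the volume bands need an average that does not yet exist), with centre-20
trimmed means per dimension.

Oriented bounding boxes are PCA boxes: axes are eigenvectors of the
centred covariance (descending eigenvalue, signs fixed toward the positive
octant with +x, +y, +z priority, determinant forced to +1), extents span
the projected min/max. The geometric box centre is the midpoint of those
extents so the box always contains its points (a centroid-centred box need
not); the tracked foot position is separately defined as the foot-cloud
centroid.

Merged frames are split by the moving-points rule: points within 20 mm of
a reference stance cloud are the non-moving leg, the rest the swinging
leg; each side must hold ≥ 30% of the points, then is outlier-filtered and
reduced to its biggest cluster. The reference is the most recent frame
within 0.5 s classified two-legs or single-leg; for two-leg frames the
reference leg is the cluster whose centroid moved least since its previous
observation — the stance leg, stationary by definition.

## Foot tracking

Average foot dimensions: each calibration leg cloud is cut into 12
equal-height horizontal slices; per-slice OBB volumes are median-filtered
(size 3, endpoints untouched); from the maximum-volume slice, scanning
upward, the first slice below 60% of the maximum marks the top of the
foot. The foot OBB's extent along its most vertical axis is the height,
the larger remaining extent the length, the smaller the width; 40
observations, centre-20 trimmed means.

The foot bottom plane is a robust consensus fit over the lowest 25 mm band
of the leg cloud: 300 seeded candidate triplets, 5 mm inlier threshold,
candidates tilted > 30° from vertical rejected. Three choices matter in
noise: candidates are scored `inliers − 3 · points_below` because a
plantar plane *supports* the foot; near-ties (within 5% of the best score)
break toward the least-tilted plane (in 5° bins) and then the lowest one,
since a partially visible wall ring admits tilted planes through a bottom
edge with equal support; and the refit offset anchors at the 10th
percentile of inlier heights — the support boundary — rather than the slab
mean. A plausibility check rejects fits whose inlier extent is smaller
than a foot (120 mm), which catches shank-only clouds.

Each frame, points within f_h above the plane are the foot; the
0.1–0.9 f_h band is projected onto the plane and 2-D PCA gives the yaw.
The box has exactly the average dimensions (smallest → height along the
plane normal, largest → length, remaining → width), base snapped onto the
plane, in-plane position from the foot-cloud centroid. Heel and toe are
the rear/front bottom-edge midpoints along the walking direction, so
|toe − heel| = f_l identically. Left/right: the walking direction is the
sign of the net AP displacement of the box-centroid tracks; walking toward
the origin, the track with the smaller median |x| (closer to the walkway
axis) is the right foot — the median, not the mean, because transient ML
excursions at coverage edges would corrupt a mean.

## Trajectory post-processing and events

Marker-less trajectories: per-coordinate 2-sigma outlier removal on
residuals from a 7-frame moving median, cubic gap fill at original
timestamps, resampling to a uniform 60 Hz grid, net-4th-order dual-pass
(zero-phase) Butterworth low-pass at 12 Hz, and resampling back — the
output keeps the input timestamps exactly. All interpolation uses
shape-preserving cubic Hermite splines (PCHIP): an ordinary cubic spline
overshoots wildly across multi-frame tracking gaps, inventing excursions
(e.g. a toe dipping below the floor mid-swing) that the low-pass filter
then preserves; the 12 Hz filter, not the interpolant, provides the
smoothing. The moving-median window must
be spike-scale: judged against a half-second trend, the 2-sigma test
(whose sigma is dominated by quiet stance samples) flags genuine
fast-swing motion and the bridging spline then rings through the landing.
Marker-style trajectories get spline gap fill plus a 20 Hz dual-pass
low-pass at their native rate.

The marker-style detector finds swing peaks (positive→negative
vertical-velocity crossings above 75% of the maximum height) and concave
dips (negative→positive crossings in the bottom 20% of the vertical
range); between consecutive peaks the deepest dip is the event (heel → FS,
toe → FO), with 50%-of-inter-peak-span rules for dips before the first and
after the last peak. For this detector to see foot off, the toe must dip
at push-off; the simulator provides this through shoe toe spring (below).

The marker-less detector estimates FS where the heel's AP motion halts and
FO where the toe's AP displacement resumes. "Stationary" is AP speed below
50 mm/s for ≥ 3 consecutive frames, with the speed taken from a symmetric
±2-frame difference (≈3x less jitter than adjacent differences, no bias at
a transition); stationary runs separated by less than 200 mm of net AP
displacement are merged, because a genuine swing advances the foot by
about a stride and smaller excursions are jitter — typically the
contralateral foot passing within the clustering tolerance. Estimates are
refined to the nearest vertical concave dip within 5 frames after FS
(before FO), but only dips with ≥ 20 mm two-sided prominence qualify:
smaller wiggles are below the depth-noise floor of the filtered vertical
signal, and snapping to them degrades an AP estimate that is already
frame-accurate. With no qualifying dip the initial estimate stands.

Validation enforces the gait-cycle order LFO → LFS → RFO → RFS: repeated
candidates of one type collapse to the one closest to the next event, then
the longest time-ordered subsequence following the succession (links
≤ 1.5 s) is kept; events not in any chain of length ≥ 2 are dropped, so an
isolated foot-off pair with its strike missing disappears entirely, while
one boundary artifact cannot erase a complete recoverable cycle.

## Stride parameters and comparison statistics

A cycle is five consecutive validated events starting at a foot strike.
Lengths are AP (y) distances between heel positions at the relevant
strikes, widths ML (x) distances — the room frame makes AP/ML exact;
3-D distances are a config switch away. Foot angle is the signed angle
between the floor-projected heel→toe vector and the walking direction.
Foot clearance is the minimum toe height over the middle 50% of swing.
Double support is the sum of the two both-feet-down periods per cycle.
Stride speed = stride length / stride time; cadence = 120 / stride time
(steps per minute).

System comparison: errors are reference minus test; samples ≥ 2 population
sigma from the mean error are removed as event-detection failures; the
inliers give mean error, population-sigma (denominator N), absolute mean
error and its sigma, min/max, Pearson r (NaN and flagged for zero-variance
inputs), and the inlier percentage. Event series from unsynchronised
systems are aligned on the first event sharing a type and a foot AP
position within 100 mm; subsequent events pair greedily by aligned time
within 0.25 s.

## The synthetic walking scene

The generator emulates the instrumented-hallway study conditions rather
than photorealistic humans. Each leg is a vertical shank cylinder (40 mm
radius) joined to a rigid foot box (250 x 90 x 80 mm); defaults describe a
comfortable able-bodied walk: 1300 mm stride, 0.55 s step, 100 mm step
width, 62% stance fraction, 180 mm peak heel rise, 25 mm minimum toe
clearance, 12 mm shoe toe spring.

Kinematics are analytic and piecewise smooth. During stance the heel is
strictly constant; the swing AP profile is a quintic smoothstep (zero
velocity and acceleration at both transitions). Heel height follows a
monotone-cubic bump peaking just after foot off — physiological, and it
keeps the mid-swing foot pitch under the plane fit's 30° tilt limit — with
a soft touchdown (no impact transient). Toe height rests at the toe-spring
height, presses down to its minimum exactly at foot off (giving the
marker-style detector its push-off dip), clears early in swing and dips to
the minimum clearance at mid-swing; the toe's AP position follows rigidly
from the heel and the pitch implied by the two heights, so
|toe − heel| = f_l exactly. Ground-truth events are the stance/swing
transitions; ground-truth parameters are computed analytically from the
profile, independent of any measurement code.

Six virtual sensors sit at the rig geometry (0.8 m height, ±900 mm across
the walkway, y ∈ {−1400, 0, +1400} mm) with a 65° horizontal field of view
(fx = fy ≈ 166 px at 212x120). All aim into a central capture zone: the
four corner sensors at 0.32 of their own y (targets ±448 mm), the two
mid-walkway sensors staggered to ∓250 mm so each end of the zone also gets
a cross view of the heel side of a landing foot. Rendering is exact ray
casting (plane, capped cylinders, oriented boxes) through each sensor's
pinhole model with unit-z ray parametrisation, so stored depths equal true
surface depths up to the 1 mm integer quantisation; Gaussian depth noise
and timestamp jitter (1 ms sigma around the nominal 1/fps spacing, shared
across sensors) are seeded. Background sequences add per-pixel noise to
the ray-cast static scene.

The default start offset (1750 mm) places all five events of one full gait
cycle inside ±850 mm of the zone centre; a five-event cycle spans about
1.5 stride lengths of event positions, so this placement is what lets a
single pass yield a complete cycle — mirroring instrumented-walkway
protocols that compute parameters from one gait cycle per pass. The
pipeline correspondingly uses only events inside a ±1000 mm capture zone.

What the simulator does not emulate: soft tissue and clothing deformation,
impact transients, sensor-specific noise (multi-path, edge fattening,
holes), torso/arm occlusion, multiple people, turning or treadmill gait.
Passing the synthetic study therefore demonstrates the geometric and
algorithmic correctness of the chain under realistic sampling density and
Gaussian noise, not robustness to every artefact of real hardware.

## Validation study and problem sizes

The acceptance study runs 10 trials of 4.5 s at 60 fps with 5 mm depth
noise on 212x120 sensors (~270 frames, ~25k pixels/sensor/frame, fused
clouds of 3–5k points), alternating which foot's cycle crosses the zone
and the walking direction; per-trial seeds derive from one study seed.
Pooled over the study, absolute mean errors are about 10–30 ms for the
temporal parameters, 5–10 mm for stride/step length, 10–15 mm for step
width and 10-15 mm for foot clearance, with all left/right labels correct —
each trial takes roughly a minute of CPU.

## Known limitations

* Foot clearance is the least accurate parameter: it carries a positive
  bias of 10-17 mm depending on the noise realisation, because the fitted
  plantar plane rides on the visible lowest cloud points (voxelisation,
  MLS shrinkage and noise rejection all lift them above the true sole)
  and plane-tilt noise narrows the measured mid-swing dip.
* The volumetric foot-height estimate absorbs part of the ankle, so the
  average foot height is ~20–30% generous; length and width are accurate
  to ~10 mm.
* Stance positions at the edges of sensor coverage are seen by fewer
  sensors and can be biased by 10–20 mm, which is the dominant term in the
  stride/step length errors.
* The event validator assumes a single walking person with a normal
  cyclic event order; pathological sequences (festination, shuffling)
  would need a different validation model.
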