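# Methods

## The problem

A two-sensor rig — visible RGB at 1280×720 and thermal infrared at
384×288 — images the soles of a subject's feet at working distances near a
fixed 800 mm focal plane. Plantar-temperature screening needs the two
spectra registered into a common frame; the registration transform depends
only on the sensors' optics and relative pose, so it can be estimated once
(at the focal plane) and reused. This package implements four estimators of
the visible→thermal transform, a STAPLE fusion of multi-rater reference
segmentations, overlap metrics, and a distance-robustness experiment, all
exercised on a synthetic rig with exact ground truth.

## Synthetic rig

Scenes live on a fronto-parallel world plane with metric coordinates
(1 grid cell = 1 mm). Each camera projects the plane with a small-angle
pinhole model: the plate scale at distance `d` is

    px_per_mm(d) = (180/π) / ((d + dz) · angres_deg)

where `angres_deg = fov_deg / pixels` is the camera's angular resolution
and `dz` a small axial (depth) offset of the sensor behind the rig's
reference plane. A camera mounted at lateral offset `B` (the baseline)
additionally shifts the scene by `B · px_per_mm(d)` pixels — the disparity.
Both effects scale as `1/d`, matching the intended geometry (scale ∝
focal_plane/distance). The product of one camera's projection with the
inverse of the other's is the exact ground-truth visible→thermal transform
at that distance; it changes with distance through the disparity (strongly)
and through the axial-offset scale ratio `d/(d+dz)` (weakly), which is what
makes a transform frozen at 800 mm degrade off the focal plane.

Default rig: visible 1280×720, 65°×40° FOV, on the rig axis; thermal
384×288, 50°×37.5° FOV, baseline 30 mm, axial offset 4 mm; focal plane
800 mm. Resolutions are the two sensors' native formats; FOVs, baseline and
axial offset are plausible values for a compact dual-camera mount, chosen
once so that the ground-truth-applied focal-plane transform loses roughly
0.02–0.03 Dice at ±50 mm — the qualitative degradation regime reported for
rigs of this type — while leaving headroom for estimator error. They are
not a claim about any physical device. A 40 mm baseline was considered and
rejected up front because the geometry alone then consumes nearly the whole
0.05 Dice budget between the focal plane and the 0.95 floor.

Other generator pieces:

* **Feet masks** (`make_foot_mask`): two mirrored sole silhouettes
  (sole + heel ellipses + five toe pads) with seed-driven size/stance
  jitter, Gaussian-smoothed at pixel scale; area fraction 10–40%.
  Foot dimensions (~220 mm long, ~95 mm wide) are adult-realistic.
* **Checkerboard** (`make_checkerboard_scene`): a rows×cols lattice of
  circular keypoints (default 5×7, 55 mm pitch) rendered with analytic
  anti-aliasing as bright blobs in the visible view and cold (dark) blobs
  in the thermal view. Detection noise is emulated by i.i.d. Gaussian
  jitter (default σ = 0.3 px) on the thermal keypoints; spurious blobs can
  be injected away from the lattice.
* **Raters** (`make_rater_stack`): pixel-independent Bernoulli raters with
  sensitivity/specificity in (0.5, 1]; defaults 0.97/0.94 sensitivity and
  0.997/0.993 specificity for the two simulated annotators.
* **Frame streams** (`make_frame_streams`): timestamps at each camera's
  nominal rate (defaults 30 and 9 fps) with optional reception jitter,
  within a 2 s buffer window.
* **Image noise**: additive Gaussian, σ = 2% of dynamic range.

What the generator does *not* emulate: perspective and lens distortion,
radiometric (temperature) content, out-of-plane foot pose, motion blur, and
spatially correlated rater errors. Passing tests therefore demonstrate the
estimators' correctness and their relative behaviour under controlled
geometric perturbations, not clinical performance on real images.

## Estimators

All four return the visible→thermal map as a 3×3 homogeneous transform;
rotation/affine centers are fixed at the image center.

**GOT.** Fixed axis-wise scaling `sx = angres_src/angres_dst` (equalizing
degrees per pixel), then a translation estimated as the component-wise
*median* of the keypoint offsets after scaling (median for robustness to a
stray bad keypoint), then a crop offset. One degree of freedom pair; any
rotation or true scale deviation (e.g. the axial offset's `d/(d+dz)`
factor) is uncorrectable by construction.

**Homography.** Normalized DLT (Hartley scaling of both point sets, SVD
null vector, `h33 = 1`) inside a RANSAC loop: minimal 4-pair samples,
symmetric transfer error (max of forward and backward reprojection
distances) against a 2 px threshold, largest consensus kept, final DLT
refit on all inliers. Degenerate samples (collinear points, detected via
the second-smallest singular value) are skipped. Defaults: 2000 iterations,
2 px threshold, minimum 8 inliers; deterministic per seed.

**ICP.** Both masks are lightly denoised (Gaussian σ = 1 thermal px,
scaled per frame, then rethresholded — pixel-independent rater noise
otherwise biases the rigid fit by up to ~0.5° of spurious rotation), the
boundary is taken as the morphological gradient (mask minus its erosion),
boundary pixels are ordered per closed contour by a nearest-neighbour walk,
and a predefined number of keypoints (default 200) is sampled at equal
arc-length steps, allocated across contours by length. The visible points
are pre-scaled by the fixed angular-resolution transform and
centroid-aligned to the thermal points — the inter-camera baseline leaves
an ~80 px offset that a nearest-neighbour loop cannot bridge, and centroid
alignment needs no calibration target, preserving the method's
checkerboard-free character. The loop alternates exact nearest-neighbour
correspondence (KD-tree) with the closed-form rigid fit (cross-covariance
SVD with determinant correction) about the thermal image center until the
RMSE change drops below 1e-6 or 100 iterations. The RMSE sequence is
non-increasing by the classic two-step argument; non-convergence returns
the best-so-far transform with `converged=False`. Fully deterministic.
Note the equal-arc sampling density bounds the achievable angular
resolution: ~4 px spacing (n = 200) supports ~0.5°, while sub-0.1°
recovery needs ~1 px spacing (n ≈ 800).

**Affine-ASGD.** Minimizes the mean squared difference between the
Gaussian-smoothed (σ = 2 px) fixed mask and the warped, smoothed moving
mask over the six affine parameters, coarse-to-fine on a 2-level pyramid.
Each iteration samples 2048 random coordinates in a 10%-padded box around
the fixed foreground and takes one preconditioned stochastic gradient step:
parameters are rescaled so a unit step displaces points by ~1 px whichever
parameter it touches. The step size follows the adaptive schedule
`γ_k = a/(t_k + A)^α` (A = 20, α = 0.602, `a` auto-calibrated so the first
step is ~0.5 px) with the time variable advanced by a sigmoid of the
negated inner product of consecutive gradients — consecutive agreement
keeps steps large, disagreement (near the optimum) decays them. Two
safeguards stabilize the schedule: a 1 px trust region per iteration, and
Polyak–Ruppert averaging of the last quarter of iterates, which damps the
terminal stochastic wander (without it the seed-to-seed Dice spread is
~0.009; with it ~0.0002). 1500 iterations per level (~1.5 s per
registration) are used rather than a few hundred for the same reason.
Stochastic but fully reproducible per seed. Like ICP it is initialized
with the angular scaling plus a centroid shift; starting masks with empty
overlap raise an error advising pre-alignment.

## STAPLE fusion

Standard binary STAPLE EM: E-step posterior
`W_i = a_i/(a_i + b_i)` with `a_i = π ∏_j p_j^{D_ij}(1−p_j)^{1−D_ij}` and
`b_i = (1−π) ∏_j (1−q_j)^{D_ij} q_j^{1−D_ij}`; M-step
`p_j = ΣW_iD_ij/ΣW_i`, `q_j = Σ(1−W_i)(1−D_ij)/Σ(1−W_i)`. Products are
accumulated in log-space; the observed-data log-likelihood is recorded per
iteration (non-decreasing). Prior: scalar mean foreground fraction across
raters unless given. Initialization p = q = 0.9999; convergence when the
largest parameter change is below 1e-6 (max 100 iterations); a final
E-step makes the returned W the posterior under the returned parameters.
All-0/all-1 raters are clamped ε = 1e-6 from the boundary with a warning.
The consensus mask thresholds W at 0.5, ties to foreground.

## Evaluation

With TP/FN/FP pixel counts against the thermal reference: Dice,
Jaccard, signed volume similarity `2(|test|−|ref|)/(|test|+|ref|)`, and
FN/FP normalized by the reference volume. The reference-volume
normalization (rather than a true background-normalized specificity) is
deliberate: frames are background-dominated, and background normalization
collapses the FP signal to ~1e-3, hiding differences between methods.

The distance experiment estimates all four transforms from the 800 mm data
(GOT/Homography from the checkerboard, ICP/ASGD from the STAPLE-fused
masks), then applies each frozen transform to every distance's fused
visible mask and scores it against that distance's fused thermal mask in
the 384×288 thermal frame. Fused references are regularized before use
(Gaussian smooth at the thermal pixel scale, scaled per frame, then
rethresholded): the pixel-independent raters leave fused boundaries far
rougher than human tracings, and without regularization the per-distance
reference noise (~0.005 Dice) is the same order as the geometric
degradation step between adjacent distances, obscuring the distance trend
the experiment exists to measure.

## Pipeline and sizes

`run_pipeline` chains generation (six distances), frame-buffer
synchronization (closest-timestamp pair via a sorted merge, ties to the
earliest timestamps), checkerboard calibration (Otsu threshold + connected
components + intensity-weighted centroids; lattice pairing via the largest
connected component of the pitch-spacing graph, PCA tilt folded to the
nearest lattice axis and limited to 5°), STAPLE fusion, the four
estimations, and the 4 × 6 × 5 metric table, writing CSV/JSON artifacts.
Everything derives from one config seed; two runs of the same config are
byte-identical. A full default run takes ~30 s on one CPU; the problem
sizes (six scenes, 5×7 board, two raters, 200 contour keypoints, 1500 ASGD
iterations/level) are the package's defaults throughout.

## Known limitations

* The synthetic geometry is similarity-only; homography's perspective
  advantage over affine cannot show up on rig scenes (it is exercised on
  synthetic projective point sets instead).
* Bernoulli raters are spatially uncorrelated — easier for STAPLE than
  human raters, whose errors are systematic along ambiguous boundaries.
* GOT's checkerboard keypoints are detected and paired automatically;
  manual keypoint selection by visual inspection is not emulated.
* Only the keypoint mapping between the two cameras is calibrated; full
  intrinsic calibration (focal length, distortion) is out of scope, as is
  anything radiometric or clinical downstream of registration.
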