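# Methods

This note documents the models, conventions, numerical choices and known
limitations of `facenav`, and what its synthetic validation does and does
not demonstrate about real hardware.

## Frames and conventions

`T_a^b` maps coordinates expressed in frame *b* into frame *a*
(`p_a = R p_b + t`), so `T_a^b · T_b^c = T_a^c`. This is the unique
convention under which both sides of the coregistration identity
`T_camera^tracker · T_tracker^marker = T_camera^headpose · T_headpose^marker`
evaluate to the camera-to-marker transform.

Euler angles are intrinsic Tait–Bryan yaw(Z)–pitch(Y)–roll(X), in
degrees, defined once in `geometry.EULER_SEQ`. The camera frame is x
right, y down, z along the optical axis (depth from camera to subject).
Published systems rarely state their angle conventions; ours is
configurable in one place rather than claimed to match any particular
software bit-for-bit. Near gimbal lock (|pitch| ≥ 89.9°) the
decomposition applies the tie-break roll := 0 and raises a
`GimbalLockWarning`; it never emits NaN.

Rotation validity is enforced at 1e-9 (orthonormality and det +1);
composition re-orthonormalises through an SVD so long chains stay closed
under the same tolerance.

## Camera model and calibration

Pinhole projection with Brown–Conrady distortion (k1, k2, p1, p2, k3):
perspective division, distortion on normalized coordinates, then the
intrinsic matrix. Undistortion inverts the polynomial by fixed-point
iteration (≤ 20 iterations, tolerance 1e-10), accurate to 1e-8 in
normalized coordinates for |k1| ≤ 0.3.

Calibration consumes board-point/pixel correspondences, not images:
corner detection is delegated to whatever produced the data (here, the
simulator). The closed form follows the planar-target construction —
normalized DLT homographies, two constraints per view on the image of
the absolute conic, intrinsics from the conic parameters, extrinsics
from the decomposed homographies projected onto the rotation group.
Refinement is Levenberg–Marquardt over all intrinsics (including the
five distortion coefficients, unless disabled) and all per-view
extrinsics, cost tolerance 1e-10. On noiseless data the closed form is
already exact to round-off; refinement leaves it there. The solver
requires ≥ 3 views; the 1000-view operational session size is a
simulator preset, not a solver minimum. Error reports carry both px
(mean absolute corner norm and RMS) and mm at the board, converting
through the per-view extrinsic depth and mean focal length.

## Head pose from 14 landmarks

The 68-point iBUG numbering is reduced to 14 structures with a fixed
index map (chin = 8, outer eye corners = 36/45, inner = 39/42, eyebrow
corners = 17/21/22/26, bottom nostril corners = 31/35, labial
commissures = 48/54, middle lower lip = 57). "Middle lower lip" is
ambiguous in the 68-point scheme; index 57 (the outer lower-lip midpoint)
is used.

The shipped anthropometric model stores named 3D coordinates in mm. Its
lateral/vertical placements and depth relief follow published
facial-anthropometry averages (inter-inner-eye-corner ≈ 32 mm, nasal
base ≈ 18 mm and lower lip ≈ 16 mm anterior to the eye-corner plane,
outer eye corners ≈ 12 mm posterior); it is a synthetic average face,
not a measured individual. The model is re-centred so a designated
origin landmark (default: chin, configurable) sits at the head-frame
origin — the reported head position is therefore that landmark's
location in camera coordinates. Because the simulator uses this same
model as ground truth, the pipeline's recovery accuracy is independent
of the default's anthropometric fidelity; fidelity only matters when
fitting real faces, where any user model can be loaded from file.

PnP is solved by DLT on the 14 (non-coplanar) points followed by LM on
the 6 pose parameters minimising pixel re-projection error, with
optional per-landmark confidence weights multiplying the residuals. On
clean data recovery is exact to optimizer tolerance (< 1e-4 mm/° in
practice, typically 1e-12). Solutions placing the face at or behind the
camera are rejected with a diagnostic; fits with re-projection RMS above
a gate (default 10 px) are flagged low-confidence and marked invalid in
tracked streams — never interpolated. Tracking offers warm starts from
the previous frame; on clean data warm and cold starts agree, and both
are provided because either per-frame or incremental solving is a
defensible real-time design.

### Session scale

A uniform scale of the model about the camera origin changes no pixel:
scaling all camera-frame points by s leaves every projection ray
unchanged, so scale and depth trade off exactly and the re-projection
error alone cannot identify the subject's scale. The session protocol
supplies the missing metric anchor — the camera–face distance of the
static acquisition (100/125/150 cm presets). The pose is fitted at scale
1 and the scale recovered in closed form as
`known_distance / mean(fitted depth)`, averaged over the session's
observations (error shrinks with more frames under pixel noise). The
scale is frozen for the session; per-frame scale would merely re-express
z-translation noise.

## Coregistration (AX = YB)

Given paired measurements `A_i` (tracker) and `B_i` (camera) of the same
head, the constants `X = T_camera^tracker` and `Y = T_headpose^marker`
satisfy `X·A_i = B_i·Y`. The rotation constraints
`vec(R_X R_Ai − R_Bi R_Y) = 0` are stacked via Kronecker products into
one 9n×18 system whose null vector is taken by SVD; the two 3×3 blocks
are rescaled by the cube root of the determinant and projected onto
SO(3). Translations then solve the induced linear system
`t_X − R_Bi t_Y = t_Bi − R_X t_Ai` by least squares (its condition
number is reported so users see why more pairs help). A joint LM pass
over all 12 parameters (rotation residuals in degrees, translation in
mm, so 1° weighs like 1 mm) refines the linear estimate; tolerance
1e-12. On clean, non-degenerate motion recovery is exact to round-off.

Degeneracy gate: the unit rotation axes of the `A_i` (taken for
rotations above 0.5°, where an axis is defined) are stacked and their
singular values normalised by √n; the second-largest must exceed 0.1,
i.e. the head motion must span at least two independent rotation
directions, which is the mathematical requirement for identifiability.
A static or single-axis session fails with a named error. The ≥ 500-pair
requirement is the operational session policy and is overridable down to
the mathematical minimum of 3.

Streams are paired by nearest timestamp with a tolerance (default half a
frame period); unmatched samples are dropped and counted in the report.

Fiducial registration (nasion + both tragi) is the closed-form
absolute-orientation solution (SVD of the cross-covariance, determinant
sign fixed), with FRE = RMS residual. Collinear fiducials are rejected.

## Filters

Savitzky–Golay: least-squares polynomial fit over a sliding window,
default order 1, window 5 — the configuration with a strong jitter
reduction and no perceptible delay at navigation frame rates. Two
evaluation modes: `causal` evaluates the fitted polynomial at the
window's newest sample (real-time default — output at time t uses only
samples ≤ t) and `centered` at the midpoint (the textbook definition,
used for offline characterization). For order 1, window 5, centered, the
weights are exactly (1/5, …, 1/5), so white-noise SD shrinks by √5;
causal weights are (−0.2, 0, 0.2, 0.4, 0.6), shrinking SD by √0.6.
During startup (and at the tail in centered mode) samples are passed
through unchanged and flagged `unfiltered` — in a medical-navigation
stream a raw pose is preferable to one fabricated from padding. Angles
are filtered on unwrapped values so a stream hovering near ±180° does
not alias through the seam. Filters never alter timestamps or counts.

Kalman: an independent constant-velocity linear filter per coordinate
(white-acceleration process noise, variances configurable). Grubbs: a
rolling-window two-sided Grubbs outlier test per coordinate (window ≥ 7
for test power, critical value from the t-distribution); flagged newest
samples are replaced by the window median. Both are declared substitutes
for unspecified originals: the state model and windowing are this
package's choices, documented as such.

## Characterization metrics

Stability: per-coordinate sample SD (n−1 denominator, fixed for
reproducibility; at n = 90 the choice is immaterial) about the mean
pose, plus the SD of the Euclidean distance from the mean position —
both are emitted because the per-axis and distance conventions coexist
in practice and reports should be explicit about which is which. Jitter
is definitionally 1.96 × SD per coordinate and is asserted as an exact
identity. Revisit accuracy reports per-visit Euclidean distance and
per-Euler-angle differences (plus the geodesic rotation angle for
completeness), with mean, SD and 95th percentile; the 3–4 mm / 3–4°
operational envelope is reported, not enforced. `target_reached` uses an
inclusive boundary (≤ 3 mm and every |Δangle| ≤ 3°), since the window is
a tolerance band.

## Synthetic scene simulator

The simulator emulates the characterization protocols: a static frontal
face at 100/125/150 cm sampled every 2 s for 180 s (90 frames);
coregistration sessions of 500 paired poses of randomised head motion
observed through the true X, Y; coil-revisit sessions of 10
repositionings, each draw gated by the 3 mm / 3° window before being
saved (as the operator protocol saves coordinates); and checkerboard
views with every corner inside the image.

Declared noise models (chosen, not inferred from hardware): isotropic
gaussian pixel noise per landmark coordinate; independent gaussian
translation noise plus small-angle gaussian rotation noise (uniform
axis) on poses, applied to the rotation and translation components
separately so rotation noise does not leak into translation through the
lever arm. All draws flow from one integer seed through fixed named
substreams, so identical configurations are bit-identical and adding a
draw site never perturbs existing streams.

Default study conditions: a 1080p consumer webcam (1920×1080, ~70°
horizontal field of view, f ≈ 1360 px, no distortion) — the class of
camera used operationally for this kind of tracking — and landmark noise
σ = 0.3 px. The static protocol is simulated with the 3D model at a
fixed pose rather than a planar photo print: the printed-photo protocol
is a hardware workaround with no desk-scale equivalent, and the
flat-photo/3D-face discrepancy is out of scope.

### What the synthetic validation shows — and does not

Passing tests demonstrate mathematical correctness (exactness on clean
data, where the estimators admit no model error), calibrated response to
known injected noise, and the qualitative behaviour of the full
pipeline: depth (z) is the least stable axis because monocular depth is
constrained only by the face's ~30 mm of depth relief against ~1 m of
range, and filtering tightens every interval. Under the default
conditions the three-trial mean filtered 95% intervals of the 100 cm
static session stay within ±2 mm and ±1° on all six coordinates, with z
the largest (≈ ±1.5–2 mm) — the same envelope and the same ordering
observed with physical cameras. They do not demonstrate performance
under real detector noise, which is temporally correlated, expression-
and illumination-dependent, and not gaussian; nor robustness to
occlusion, non-neutral expressions, or detector failure modes. Absolute
hardware numbers should be re-measured on hardware.

## Problem sizes and runtime

Default validation sizes: 500 coregistration pairs (20 Monte-Carlo
repetitions for noise response), 200 repetitions for PnP noise
anisotropy, 10 calibration views (the 1000-view session remains a
preset), 90-frame static sessions with 3 repeated acquisitions, 10-visit
revisit sessions, 10,000-sample filter noise runs. The whole suite runs
in about half a minute on one CPU; `scripts/acceptance.py` in a few
seconds.

## Known limitations

- The shipped face model is a synthetic average; subject-specific models
  must be supplied for metric accuracy on real faces.
- Scale estimation requires the protocol's known camera–face distance;
  without any metric anchor monocular scale is unidentifiable in
  principle.
- The Kalman and Grubbs variants are reference implementations with
  simple state/window models, not tuned clinical filters.
- No face detection or landmark detection is included; the package
  starts from landmark coordinates.
- Euler-angle reports are convention-dependent; cross-software
  comparisons must align conventions first (the geodesic rotation
  distance is convention-free and reported alongside).
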