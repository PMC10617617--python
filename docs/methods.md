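# Methods

This note documents the model, the numerical procedures, the synthetic-data
generator and the design choices behind `whiskmorph`, in enough detail that
a user can judge what the passing test suite does and does not establish.

## Coordinate system and basepoint coordinates

The head-centered frame is constructed from the digitized data themselves,
with no external reference:

1. **Origin** — the arithmetic mean of all whisker basepoints matched
   across the left and right arrays. An identity digitized on only one
   side is omitted, so a missing whisker cannot drag the origin laterally.
2. **Horizontal plane** — a total-least-squares plane (SVD of the centered
   cloud) is fitted to each whisker row's basepoints, pooled across both
   sides; the *average row plane* has the renormalized mean of the
   sign-aligned unit normals and passes through the mean row centroid.
   Total rather than ordinary least squares because digitizer noise is
   isotropic in x, y, z. Rows with fewer than three non-collinear
   basepoints are skipped; fewer than five rows is tolerated.
3. **Axes** — z is the dorsal plane normal; x is the line between the
   left and right array centroids *projected into* the plane (the line
   need not lie in the plane; projection keeps the frame orthonormal and
   is rejected with an error if the line is within 5° of the normal);
   y = z × x points rostrally.

Basepoints are reported as (r_bp, θ_bp, φ_bp): radius from the origin,
horizontal angle from +x (rostral positive), and elevation (dorsal
positive). Left-side whiskers are mirrored across the y–z plane after
frame construction and before any pose fitting, so all equations describe
a right array; the mirrored left frame intentionally violates the
right-hand rule.

A consequence worth knowing: the average row plane of a realistic array is
not exactly the plane the generating model used, because r_bp varies
within a row (the snout narrows rostrally), tilting each row's fitted
plane slightly. The residual frame tilt after averaging is a few tenths of
a degree and is a property of the procedure itself — real digitized data
carry the same tilt, and the model equations are defined in the frame the
procedure yields.

## 2D shape: arclength and curvature coefficient

Scanned whisker traces (2400 dpi, 25.4/2400 ≈ 0.0106 mm/px) are smoothed
in y with a 20 px centered moving average before any measurement. The
moving average shrinks symmetrically at the ends (even widths are rounded
down to odd), so endpoints are preserved and a linear trace passes through
unchanged; this matters because an endpoint-biased filter systematically
shortens every trace. Arclength S is the sum of segment lengths of the
smoothed polyline. The smoothing step is what makes polyline arclength
usable at all on quantized traces: the raw staircase inflates arclength by
an amount that does not vanish with finer pixels.

For the curvature coefficient the trace is put in standard pose: basepoint
at the origin, the proximal 8 % of arclength rotated onto +x (the
total-least-squares direction of that segment, pointed away from the
base), reflected if needed so the bulk of the whisker lies concave-up.
y = A·x² is then fitted (closed form, A = Σx²y / Σx⁴) to the proximal 65 %
of arclength — only that much of a whisker stays planar. The 8 % default
was selected by the packaged grid search (1–30 % in 1 % steps, smallest
mean fit MSE, ties to the smallest fraction). Because the proximal part of
a parabola has nonzero mean slope, this alignment leaves a small
procedure-dependent bias in A for traces with no straight proximal run;
the measured A is exactly invariant to rigid motion and reflection of the
input, which is the property the pipeline relies on.

### The A–S upper bound

Observed (S, A) pairs admit an upper-bound curve, fitted by sliding a 4 mm
window over S in 1 mm steps, taking each window's maximum A at the S where
it occurs, and fitting A_ub(S) = c0·exp(c1·S) by least squares on log A.
The packaged mouse bound has c0 = 0.012 mm⁻¹ — its value at S = 0, the
intercept on the curvature axis. `solve_S_from_bound` inverts the bound
numerically for curvatures above the intercept and assigns the longest
observed arclength otherwise (the boundary case joins the fallback
branch). The exponential family with positive c1 is the only single-form
choice under which "solve for S when A exceeds the intercept, undefined
below it" is well posed; the empirical envelope of a dataset in which
short whiskers are the most curved is decaying, and `fit_upper_bound`
accepts either sign of c1. This is the one place where the published
model's functional form had to be chosen rather than verified, and the
choice follows the solvability contract.

Mock whiskers (`make_mock_whisker`) are points on y = A·x² with a
prescribed total arclength, the x-extent found by Brent inversion of the
closed-form parabolic arclength integral; sampling is uniform in
arclength, so measured arclength and refitted curvature both round-trip.

## 3D emergence angles

The idealized whisker is a planar parabola of arclength S and coefficient
A, base at the origin, proximal tangent along −y, concave toward −z. It is
rotated extrinsically about the global axes in the order y (roll ζ_w),
x (pitch φ_w), z (yaw θ_w). With right-handed rotation matrices the
composite is R = R_z(θ_w)·R_x(−φ_w)·R_y(−ζ_w): the pitch and roll
arguments are negated so that the angles mean what the field convention
says — φ_w = +90° points the whisker dorsally, ζ_w = 0/90/180° is concave
down/forward/up. (With unnegated right-handed pitch, +φ_w would point a
caudally-directed whisker ventrally.)

Point clouds are preprocessed by sorting along distance from the
basepoint, smoothing each coordinate (window of five points, symmetric
shrinking ends), resampling at 0.5 mm arc steps and translating the base
to the origin. The fit minimizes the mean squared distance between cloud
and model points matched *by index* from the base, with both polylines
resampled at the same 0.5 mm step and the model passed through the
identical smoothing + chordal-resampling transform; indices beyond the
shorter polyline are matched to its final point, so arclength mismatch is
penalized rather than silently truncated. Matching by index (not nearest
neighbor) keeps the objective sensitive to sliding along the whisker.

The optimizer is bounded Powell from systematic starts: yaw/pitch
initialized from short and long proximal-segment directions, roll started
in each of the four quadrants, arclength from the cloud's polyline length,
and curvature from the cloud's sagitta (h ≈ A·(S/2)² for a parabola). A
cheap coarse pass (4 Powell iterations per start) ranks the basins; the
best candidate is refined to convergence, and if the refined optimum is
not an exact fit the best candidate from a different roll quadrant is
refined too — the roll objective is the multimodal one. On noiseless
synthesized clouds the recovered parameters match the truth to better than
1e-2° / 1e-3 mm across the full parameter range, and the returned optimum
is never worse than the objective at the true parameters.

Roll is reported as missing for whiskers shorter than 8 mm and, beyond
that rule, when A·S < 0.05 (a dimensionless sagitta proxy): a nearly
straight whisker's twist is unidentifiable, and fitting it anyway returns
noise. This floor matters for interpreting the error simulation below.

### Digitization-error simulation

`simulate_measurement_error` perturbs every point of a synthesized whisker
(including the basepoint) independently and uniformly by ±0.5 mm per axis
— the digitizing arm's measured resolution; uniform was chosen over
Gaussian as the natural reading of "±0.5 mm" — then re-derives the
spherical basepoint coordinates and re-fits the pose. The reproducible
ordering: basepoint angles move by at most a few degrees (bounded by
noise/r_bp); emergence angles move much more, the more so the shorter the
whisker; and the twist angle is by far the least stable, with extreme
errors arising from whiskers whose curvature is barely above the
identifiability floor.

## Statistical modelling

Outlier screening: for each measured parameter separately, whiskers are
grouped by (row, column) identity pooled across animals; in groups of at
least three, values beyond 2 sample standard deviations from the group
mean are dropped. The filter is a single pass — reapplying it would remove
more — and every parameter is screened, including basepoint coordinates
later used as predictors (leaving predictor outliers in place attenuates
slopes via errors-in-variables).

Per-animal forward selection: univariate first-order screens in each
candidate predictor admit terms at p ≤ 0.05; admitted terms are fitted
jointly and pruned until all are significant; squared terms are considered
only for admitted first-order terms and accepted only when all
coefficients remain significant *and* AIC drops by more than 2; order
never exceeds two. For arclength and curvature both raw and log-response
branches are fitted (their distributions are right-skewed); the
exponential arclength model is the log branch with a linear θ_bp term.

Consensus: a term is a candidate for the combined model only if it was
selected in at least six individual animals (the threshold is six
regardless of whether seven or eight animals contributed), and squared
terms only if themselves supported, capping the consensus order at the
supported order. Candidates are re-selected on the pooled data with the
same gates, so a retained term is re-checked for significance. Raw vs log
branch is decided at the consensus stage by AIC with the 2·Σlog(y)
Jacobian correction added to the log branch, which puts both likelihoods
on the raw response scale; within a branch, statsmodels' Gaussian AIC is
used unchanged (any additive constant cancels in ΔAIC).

## Generation and comparison

`generate_array` evaluates, per identity in the species layout: θ_bp from
column, φ_bp from row, r_bp from the angle form (it transfers across
species with different layouts), S and A from θ_bp, θ_w from the reduced
horizontal-angle model, φ_w from the elevation model, and ζ_w from the
reduced twist model — except for the A row and each row's rostral-most
column, which the reduced twist model excludes; these fall back to the
full model and carry a low-confidence flag, because the generator must
orient every whisker. Left whiskers are exact mirrors.

Basepoint area/density projects one side's basepoints into the y–z plane
and uses the convex hull area — a deliberate choice the density numbers
depend on; a concave-hull definition would give smaller areas and higher
densities.

`compare_species` reports, for features present in both landmark sets,
rostro-caudal (|y|) and bilateral (|x|) distances from the
basepoint-centroid origin as per-feature ratios, a through-origin slope
(Σxy/Σx²) and an ordinary affine fit, plus the scale-free angular overlay
(θ, φ per feature). `register_landmarks` is standard Kabsch: rotation from
the SVD of the cross-covariance of centered correspondences, no scaling,
with the determinant correction against reflections.

## The packaged coefficient sets

`data/mouse_synthetic.json` and `data/rat_synthetic.json` are **synthetic
reconstructions**, not transcriptions: the source study's displayed
equations were not available to this implementation, so coefficients were
chosen once to reproduce every published summary value — the ~11.7 mm
arclength at θ_bp = 0 and the ~2–30 mm (mouse) / 10–60 mm (rat) arclength
ranges, the 0.012 mm⁻¹ upper-bound intercept, the elevation-row slope
(mouse CI midpoint −16.785; rat forced-linear slope −17.4 inside its CI),
the column-group means of the horizontal emergence angle (mouse 120°/59.3°
for columns 6–7/1–2; rat 97.0°/51.0°), the ~4° elevation offset between
species, the ~56 % mean radial-size difference, and the 2.03 / 1.49x+1.45
/ 2.35 facial and diameter scalings. In addition, the basepoint-equation
intercepts are solved so that the generated array's basepoint centroid
sits exactly at the origin — the coordinate convention real digitized data
satisfy by construction. The files are versioned and checksummed; the
loader rejects a file whose equations disagree with its checksum, and
fitting never overwrites packaged sets. Conclusions that depend on the
*specific* coefficient values (not on the pipeline) should be re-derived
from the study's deposited data (DOI 10.5281/zenodo.7992354).

## The synthetic-data generator

`make_ground_truth` emulates the study design: 8 animals, the species'
row/column layout on both sides (~30 whiskers per side), a per-animal
lognormal(0, 0.06) head-size factor multiplying r_bp and S, independent
Gaussian residuals per parameter, and 4 % gross outliers displaced by six
residual SDs to exercise the 2-SD filter (matching the study's ~3–5 %
removal rates). The default residual SDs — θ_bp, φ_bp 4°; r_bp 0.45 mm;
log-S 0.12; A 0.004 mm⁻¹; θ_w 8°; φ_w 3.5°; ζ_w 12° — reproduce the
qualitative fit-quality ordering of real arrays (elevation angle tightest,
twist loosest, radius noisier than the basepoint angles, curvature scatter
large relative to its range). `digitize` renders whiskers as 3D polylines
of 4–60 points, perturbs every point uniformly by ±0.5 mm per axis, adds
facial landmarks from the template and emits each animal in a random rigid
pose, so frame construction is genuinely exercised. `render_scan`
resamples a planar shape to pixel spacing, quantizes to the pixel grid and
trims 0–2 px from each end (the ~42.4 µm arclength error model).

What the generator does *not* emulate: non-parabolic distal whisker shape
(real tips leave the plane of intrinsic curvature; the model extrapolates
the proximal fit), per-animal correlation structure beyond a scalar size
factor, digitizer error that varies with reach or angle, missing or
mislabeled whiskers, and scan artifacts beyond quantization and endpoint
loss. Passing tests therefore establish that the pipeline inverts its own
generative assumptions at realistic noise — not that those assumptions
exhaust real data.

## Problem sizes and runtime choices

The test suite runs the pose-identity sweep at 100 random parameter
points, the consensus-recovery check on the full default dataset (8
animals × 60 whiskers, on the ground-truth parameter table), the type-I
check at 200 replicates, and the digitized end-to-end pipeline at 3
animals with a support threshold of 3 — the per-whisker pose fit is the
expensive step (~1 s per noisy whisker), and 3 animals already give
coefficient standard errors several times smaller than the recovery
tolerances. Short rostral whiskers (S < ~6 mm, a handful of noisy points)
fit poorly — their errors dominate the tails of every end-to-end
comparison, which is faithful to the measurement problem and is why the
twist angle carries an 8 mm rule and the A row is excluded from the
reduced twist model.

## Known limitations

* The curvature coefficient from the 2D chain carries the alignment bias
  described above (zero for whiskers with a straight proximal run).
* The 3D pose fit's S and A are noisier than scan-derived values; the
  study measured 2D shape from scans, and so should users with scans.
* The packaged coefficient sets are reconstructions (see above); the
  pipeline, not the coefficients, is the tested artifact.
* Emergence angles are resting angles measured under anesthesia; no
  whisking kinematics are modelled.
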