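# Methods

This note documents the models implemented in `scapstab`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish.

## Landmark template and synthetic cohorts

All shape analysis operates on 29 named landmarks
(`data/scapula_template.json`). The template is a hand-built, schematic
right scapula in millimetres (canonical frame: x lateral, y superior,
z posterior; origin at the glenoid rim centroid). It is deliberately not
derived from any imaged specimen: eight glenoid-rim points on a 32 x 24 mm
ellipse, three acromial points, two coracoid points, four supraspinous
fossa perimeter points, three medial-border points, and assorted anchors
(spine, inferior angle, blade centre, tubercles, scapular notch, teres
major origin). The landmark *names* are the contract: every metric and
frame construction looks up named anchors, so a missing landmark fails
loudly with its name.

Synthetic cohorts are `template + effect_scale * effect_vector` (FTT
group) or `template` (controls), plus isotropic Gaussian landmark noise
and optional nuisance similarity transforms: rotations drawn uniformly
over SO(3), translations uniform in a +/-50 mm cube, scales log-uniform in
[0.8, 1.25] (symmetric about 1 on the log scale, no degenerate flips).
Defaults are 91 controls vs 24 FTT — the unbalanced cohort composition the
method is meant to face — with `noise_sd = 1.5` mm per coordinate. That
single noise term stands in for the sum of digitization error (sub-mm) and
interindividual shape variability (several mm at most landmarks); it is
the one knob that sets how separable the default cohort is.

The default effect vector bundles the qualitative tear-associated suite in
one displacement field: at unit scale the glenoid block (rim + adjacent
tubercles) is anteverted 6 deg and superiorly inclined 2 deg about the rim
centroid and shrunk 3.5% in-plane; the fossa anteroposterior extent is
multiplied by 0.8; the lateral acromion moves 2 mm laterally while the
acromial AP span contracts by 15%; the coracoid tip shifts
anteroinferiorly and the spine 1 mm cranially. These magnitudes were
chosen to sit in the clinically reported range for the discrete metrics
(a few degrees / about a millimetre per metric) and are fixed; tests
assert directions of effect, never these magnitudes.

**What the generator does not emulate:** correlated, spatially structured
biological variation (noise is landmark-wise isotropic), left scapulae,
sex or age structure, segmentation artefacts, and any real covariance
between shape features beyond the single injected axis. Passing tests
therefore demonstrate the *machinery* — alignment invariance, model
recovery of a known axis, correct geometry and signs — not clinical
performance on real anatomy.

## Procrustes superimposition

Full similarity GPA: centre, scale to unit centroid size, rotate to the
running mean by the Kabsch solution with a determinant correction
(reflections never used, preserving anatomical handedness), re-estimate
the mean, normalized back to unit centroid size each sweep; convergence
when the mean moves less than 1e-10 RMS (at most 100 sweeps,
non-convergence flagged on the result, not raised). Coincident-landmark
and coplanar configurations are rejected as degenerate. No tangent-space
projection is applied — the discriminant model consumes raw Procrustes
coordinates; at the shape variation scales involved the curvature of
shape space is far below the effects studied.

## PLS discriminant analysis

PLS1 with X-block deflation on the flattened 87-coordinate shape block;
columns are centred but not autoscaled (Procrustes coordinates share
units; autoscaling would inflate low-variance landmarks). The first weight
vector is proportional to the group-mean difference direction, which is
what makes direction-recovery tests meaningful. Regression coefficients
for m modes are W (PᵀW)⁻¹ q.

Model selection mirrors the standard protocol: M = smallest mode count
whose cumulative X-variance reaches 70% (capped at 14 when emulating the
reference run); LOOCV over m = 1..M; classification rule y > 0.5 is FTT
(the tie y = 0.5 goes to control, since only strict inequalities are
specified); the optimal m maximizes balanced accuracy with ties to the
smaller model. Precision with zero predicted positives is reported as 0
and flagged. Null models permute labels (group proportions preserved
exactly) and rerun the *entire* pipeline, including mode-count selection;
Z = (true − null mean)/null SD and one-sided p from the standard normal
upper tail. A zero null SD yields an infinite Z and is flagged rather than
hidden. Group-associated shapes are the group-mean shapes projected onto
the m retained modes (the oblique PLS projector); their group-size
weighted average is the grand mean exactly, and at full rank they
reproduce the original shapes.

## Thin-plate splines

The 3D biharmonic interpolant U(r) = r (the 2D r² log r kernel does not
apply in three dimensions), no regularization: landmarks are interpolated
exactly, so warped meshes keep vertex correspondence. Bending energy is
−wᵀKw (the conditionally positive-definite form uses −r), clamped at zero
against roundoff; the kernel weights satisfy the four polynomial
annihilation constraints, which makes the warp asymptotically affine far
from the landmarks. Coincident source landmarks are reported by index
pair; coplanar sources are rejected (singular 3D system). Mesh warping
touches vertices only and passes non-watertight meshes through with a
warning.

## Discrete scapular metrics

Landmark-only constructions (degrees, input length units): CSA at the
inferior rim between rays to the superior rim and the lateral acromion;
inclination as the signed blade-plane angle of the SI rim chord vs the
scapular SI axis (positive = face tips superior); version as the signed
transverse-plane angle of the rim-fit normal vs the scapular ML axis
(anteversion positive); height/width as rim extents along the in-plane
principal axes, tie-broken to the scapular SI direction when the top two
rim variances differ by less than 5% (near-circular rims); coverage as the
angle subtended at the glenoid centre by the anterior and posterior
acromial points; lateral acromion ratio as lateral acromial overhang over
scapular width x 100. All metrics are invariant to rigid motion and
uniform scale (frame recomputed alongside) except height/width, which
scale linearly. Under a true left-right mirror measured in the
right-scapula convention the signed angles negate and the unsigned ones
are preserved; the frame constructor itself rejects mirrored landmark sets
so left scapulae cannot silently enter a right-handed analysis.

## Kinematics and humeral placement

Bone frames follow the ISB spirit: scapular y along the medial border,
z normal to the blade plane oriented posteriorly via the spine, x = y x z
lateral; humeral y along the shaft with the plane fixed by the epicondylar
axis. Poses are intrinsic Y-Z-Y (elevation plane, abduction, axial
rotation); the inverse is taken on the canonical branch (abduction in
(0, 180)) and flags gimbal poses. Sign conventions: positive plane is
anterior; positive axial is internal, so 50 deg external rotation is
axial = −50 and "added internal rotation" perturbations are positive
offsets.

Humeral placement is deliberately simplified relative to proximity-driven
translation optimization: the head centre sits on the glenoid-centre
normal at `head_radius + gap` (gap default 1 mm), so the joint stays
congruent and placement is rotation-only. Range-of-motion feasibility uses
an analytic impingement model instead of mesh-mesh collision: humeral test
points (greater/lesser tuberosity bumps at 1.05 R, shaft-axis samples with
the shaft radius) against a glenoid slab (2 mm clearance within the rim
footprint plus 4 mm margin) and acromial/coracoid obstacle spheres. The
kinematic neutral pose is the centroid of the feasible triples on a
10-degree Euler grid (plane −60..90, abduction 10..140, axial −90..90).
This model is coarse but has the right structure: a mirror-symmetric
construct (no coracoid, symmetric humerus) yields exactly zero neutral
plane and axial rotation, and anteverting the glenoid shifts the neutral
pose anteriorly and into internal rotation — the directions reported for
tear-associated shapes — though with smaller magnitudes than a
proximity-optimized model produces.

## Fibre model and stability ratios

Fifty fibres: 30 deep sampling the full fossa origin loop at equal arc
length, 20 superficial on the contiguous superior half-arc, each paired to
the insertion loop at the matching normalized arc-length fraction; the
anterior/posterior split is a rank split at the median AP origin
coordinate (exactly 25/25 on symmetric geometry). Wrapping treats the
humeral head as its fitted sphere, where the shortest path is exact: the
wrap plane contains both endpoints and the centre, giving the
tangent–arc–tangent construction; the path length is measured from the
constructed tangent points and arc, and the 100 nodes are spaced equally
by arc length. Attachment points may sit up to 2% of the radius below the
idealized sphere (arc-length interpolation between perimeter points);
deeper endpoints are rejected as inside the obstacle. A watertight scapula
mesh can additionally be enforced by projecting offending nodes out along
the nearest-surface direction (50 fixed-point iterations, tol 1e-6); the
default synthetic scenes never trigger it, since the fossa sits above the
blade surface.

The finite-element sheets of the full treatment are replaced by a
lateral-coherence regularizer: interior nodes of each fibre are blended
toward the mean of the within-sheet neighbours (weight default 0.1,
weight 0 = independent shortest paths), then pushed back out of the sphere
and resampled. This reproduces the sheets' geometric role — keeping
adjacent fibres from splaying over convex surfaces (adjacent-arc
divergence decreases monotonically in the weight) — without material
mechanics, which the geometry-only stability question does not need.

Effective endpoints are the contact-run boundaries: the last node of the
scapula-contact run starting at the origin and the first node of the
humerus-contact run ending at the insertion (contact tolerance default
0.5% of the head radius, capped at 5% of path length so "everything
touches" degeneracies are rejected); unwrapped fibres fall back to nodes
0 and 99. The line-of-action points from effective insertion to effective
origin (the force the fibre applies to the humerus). The glenoid frame is
the rim principal-axes triad (compression = least-variance axis directed
medially; SI = greatest-variance axis directed superiorly, seeded from the
scapular frame when the rim is near-circular within 5%; AP completes the
triad anteriorly). Fibres with a non-positive compressive component are
flagged destabilizing and excluded from ratio summaries instead of
reporting signed infinities. Tension is a length check against a slack
length defaulting to each fibre's length at the first (10 deg) pose.

## Pipeline, determinism, problem sizes

`run_full_analysis` chains all stages and writes CSV/JSON artifacts plus a
manifest; all randomness flows from the single mandatory seed through
`numpy.random.default_rng`, so identical config + seed reproduce
byte-identical tables (fixed float formatting, sorted JSON keys). The
default perturbation set applies {+5, +10} deg anterior plane, {+5, +10}
deg internal rotation, and the two combined offsets to the tear-like
shape only. Default problem sizes — a 115-specimen cohort, 20 null
replicates, 19-pose paths with 50 fibres, a 4,200-pose ROM grid — complete
in well under a minute on one CPU; the test suite uses smaller cohorts
where full size adds nothing to the property being checked.

## Known limitations

* The impingement model and constant-gap placement are stand-ins for
  proximity-driven translation optimization; neutral-pose magnitudes are
  smaller than optimized models report, and only their signs are asserted.
* Sphere-only wrapping ignores scapular-side obstacles in the default
  scenes; the mesh projection fallback is untriggered there.
* The synthetic cohort has a single group-difference axis, so PLS mode
  selection on defaults tends to pick small m; real cohorts spread group
  differences across many correlated modes.
* Stability ratios describe force *directions* only; no muscle force
  magnitudes, net joint force, or dislocation limits are computed (an
  experimental limits-of-stability ellipse can be overlaid downstream but
  none is shipped).
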