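# Methods

## Coordinate conventions

All interfaces use world coordinates in LPS millimetres, the native CT frame.
Voxel indices are 0-based, continuous, and refer to voxel centers:
`world = origin + direction · (spacing ⊙ index)`. A `RigidTransform` maps its
source frame into its destination frame; chains compose by matrix product.
Volumes round-trip through NIfTI and NRRD via SimpleITK with metadata intact.

## Skin segmentation

`segment_body` applies, in order: threshold (default −300 HU, midway between
air and soft tissue and configurable because patient habitus and protective
wrapping shift the skin boundary), largest 26-connected component,
morphological closing with a metric ball (default radius 10 mm), inversion,
largest 6-connected component of the inversion (the outside air), and a final
inversion. The closing seals narrow skin openings such as the nostrils so the
subsequent fill step treats the airways and lungs as interior cavities; the
complementary 26/6 connectivity pair avoids topological paradoxes between
foreground and background.

Closing is implemented with Euclidean distance transforms using the voxel
spacing as sampling, which makes the "1 cm kernel" a true metric ball on
anisotropic grids; the mask is padded by the ball radius first, because a
dilation clipped at the array border would leave the erosion without
background there and spuriously inflate the result. The pipeline guarantees a
single foreground component with no enclosed background.

`extract_surface` contours the mask at the 0.5 level with marching cubes
after Gaussian smoothing (default σ = 2 voxels). Contouring the raw binary
mask produces staircase facets that overestimate curved areas by up to ~30 %
and give noisy normals; the smoothed isosurface tracks the true boundary to a
fraction of a voxel and its field gradient yields vertex normals accurate to
a few degrees at 3 mm voxels (the dominant error term in the insertion-angle
scalar). Normals are oriented outward by testing offset points against the
mask.

## The insertion heat map

Candidate entries are exactly the mesh vertices; mesh density therefore
controls planning resolution. Categories are assigned with precedence
OUT_OF_RANGE → OCCLUDED → DENSE_BLOCKED → MARGIN_BLOCKED → ANGLE_BLOCKED →
UNREACHABLE → FEASIBLE, mirroring the order of the planning steps; every
vertex gets exactly one category, and depth/angle/max-HU scalars are stored
for all in-range vertices.

**Maximum HU projection.** The HU profile along a ray is the trilinear
interpolant, which is piecewise smooth but has kinks at cell boundaries and
can form peaks narrower than the voxel size where a ray grazes the corner of
a dense cell (slopes of ~100 HU/mm on sharp phantoms). Fixed-step sampling
at any practical rate can miss such peaks entirely, so `ray_max_hu` samples
coarsely (default min(spacing)/2), bounds the field over each interval with a
5³ maximum-filtered copy of the volume, and subdivides only the intervals
whose bound exceeds the running maximum, branch-and-bound style, down to a
0.002 mm tolerance. The result is the true profile maximum to within the
local slope times the tolerance, at a cost proportional to the number of
dense-structure crossings. The vectorized map-building path uses the same
bound-guided scheme with a single 20× refinement level, which is ample for
classification against the dense threshold. The dense-structure threshold
defaults to 300 HU (above soft tissue and blood, below cortical bone) and is
configurable for implants or contrast.

**Occlusion.** A vertex is occluded when body tissue lies on the outward
continuation of the insertion axis within the instrument clearance (default
190 mm, the guide-needle length). Membership is tested by trilinear
interpolation of the mask (> 0.5); sampling starts two voxels past the entry
because the smoothed isosurface can sit up to a voxel inside the interpolated
binary boundary, and without the guard the body's own surface shell reads as
an obstacle. Detached structures thinner than that guard would go undetected;
at default spacings the guard is 4–6 mm.

**Safety margin.** The 5 mm margin around dense-blocked vertices is a
Euclidean distance in 3-D between mesh vertices (k-d tree query), not an
image-space dilation, making the contract exact and independent of mesh
resolution.

**Cost and selection.** q = 0.5·d/l + 0.5·a/90 with both terms scaled by a
common positive normalization constant fixed to 1 — any positive value
rescales every q identically and cannot change the ranking, which is all the
planner uses. Angles at or above 90° are excluded before scoring: the
normalization is undefined beyond 90° and grazing insertions are physically
meaningless. Ties in q are broken by smaller depth, then smaller vertex
index, so selection is deterministic.

## Reachability

The planner needs only a predicate "can the robot realize this
entry→target insertion"; the oracle interface accepts any kinematics engine.
The shipped geometric default tests (i) a reach annulus around the robot
base (defaults 300–820 mm, an arm-scale envelope; tests set them explicitly),
(ii) a straight retracted approach corridor that must not intersect the skin
mesh (vectorized Möller–Trumbore segment test; hits within 1 mm of the entry
are its own triangles) or the gantry half-space, and (iii) the target's
clearance of the gantry half-space. It deliberately omits joint limits,
self-collision and trajectory feasibility — those belong to the pluggable
engine.

Grid evaluation bins candidates on the two CT axes spanning the largest face
of the mesh bounding box at the grid spacing (default 30 mm). Because a
closed skin surface projects its near and far side into the same planar
cell, cells are additionally split along the remaining axis at the same
spacing; without this, no grid spacing — however fine — could reproduce
per-vertex evaluation, since opposite sides of the body would always share a
verdict. The oracle runs once per non-empty cell at the candidate nearest
the cell center; cells are independent, so evaluation parallelizes.

## Hand-eye calibration (QR24)

The model is B<sub>i</sub>·X·C<sub>i</sub> = Y with B<sub>i</sub> the robot
pose (base→end-effector), C<sub>i</sub> the tracked pose (marker→camera),
X = end-effector→marker and Y = base→camera. All 24 parameters of (X, Y) —
two 3×3 rotation blocks and two translations — enter one stacked linear
system: per pose, `(R_C^T ⊗ R_B) vec(R_X) − vec(R_Y) = 0` (9 rows) and
`(t_C^T ⊗ R_B) vec(R_X) + R_B t_X − t_Y = −t_B` (3 rows), solved by least
squares without orthogonality constraints; dropping the constraints is what
makes the problem exactly linear. Each rotation block is then projected onto
the nearest proper rotation (SVD polar factor, det forced +1), and residuals
are reported after projection as per-pose translation norms and geodesic
rotation angles — the same units a hardware calibration reports.

Degeneracy is detected twice: relative rotations of the robot poses must
span at least two independent axes (the classic unobservable configuration
is all rotations about one axis), and the stacked system must have full
rank 24; either failure raises a calibration error with condition
diagnostics. On noiseless synthetic sets the recovery is exact to numerical
precision; at 0.1 mm / 0.1° tracking noise on 60 poses, recovery errors stay
well under 0.1 mm / 0.01°.

## Fiducial registration

The registration phantom is a 4×6 grid of 24 steel balls (nominal pitch
20×18 mm) with fixed in-plane jitter of up to ±3 mm and an irregular
assignment of the two radius classes (12× 2 mm, 12× 5 mm). The jitter and
the class pattern break the grid's symmetry so that each ball's sorted
distances to same-class and other-class neighbours form a unique,
rigid-invariant fingerprint. Detected components are split into radius
classes by volume, matched within class by assignment on fingerprint
distance (tolerance 1 mm — far above centroid quantization, far below the
pitch), and the match is verified against the full pairwise-distance matrix.
If forbidding any matched pair still admits a complete alternative
assignment within tolerance, the correspondence is ambiguous and the match
is refused rather than guessed.

Centroids are unweighted means of component voxel centers (intensity
weighting is an option flag). The rigid fit is the Kabsch/Horn solution with
det +1 correction; collinear sources are rejected. At 0.6 mm rasterization
the end-to-end chain recovers the ground-truth base→CT transform to
~0.02 mm / ~0.02°, dominated by centroid quantization averaged over 24
balls.

## Placement evaluation

The biopsy center is taken 10 mm beyond the detected guide-needle tip along
the insertion direction — the sampling notch extends past the cannula — with
the sign convention exposed as a flag. The error vector from target to
center splits into a signed axial component along the needle axis and a
non-negative lateral component normal to it; dev3d² = lateral² + axial²
holds to numerical precision and all three are invariant under rigid motions
of the scene. Summaries report per-site mean ± sample SD (n−1); single-
member groups are flagged rather than given a fake SD.

## Synthetic phantoms

The generators exist to make every stage testable by recovery against known
ground truth. `make_phantom` rasterizes ellipsoids, cylinders, torus-segment
rib arcs, a detached arm cylinder, and a sub-centimetre "nostril" air
channel, with a voxel-center-inside membership rule so the analytic masks
are voxel-exact. Default HU levels (air −1000, lung −800, soft 40, bone
700, steel 3000) are physically typical and strictly ordered across the
segmentation and dense thresholds. Pose pairs place measurement noise on the
tracked poses (random-axis rotation with angle |N(0, σ_r)|, translation
N(0, σ_t) per component). All generators are pure functions of (spec, seed).

What the phantoms deliberately lack: image noise, partial-volume blur, beam
hardening, anatomy-shaped organs, and deformation between scans. Passing
tests therefore demonstrate the correctness of the geometry, the planning
logic and the estimators under ideal imaging — not robustness to scanner
physics, patient motion, or segmentation of realistic anatomy. HU
transitions in the phantoms are single-voxel sharp, which is *harder* than
real data for the ray-projection maximum (sharper kinks), and *easier* for
segmentation (no threshold ambiguity).

## Problem sizes and runtime

The validation suite uses 64³ phantoms at 3 mm spacing for planning tests
(meshes of ~7 000 vertices), 128³ at 1.5 mm for segmentation fidelity, and
0.6 mm grids for fiducial rasterization — sizes chosen so the full suite and
the acceptance script each complete in a few minutes on one CPU while
keeping voxel-scale tolerances (half-voxel centroids, 5° normal
discretization) meaningful. The acceptance script's reachability
configuration parks the robot 600 mm lateral of the target with a 650 mm
reach cap and a gantry plane 70 mm head-ward, a plausible table-side layout
that leaves part of the hand-feasible surface out of robotic reach.

## Known limitations

- Occlusion cannot detect obstacles thinner than the two-voxel surface
  guard, and uses the body mask rather than a second threshold pass.
- The default reachability model knows nothing of joint limits or the
  end-effector envelope; conclusions about robotic coverage transfer to real
  systems only through a plugged-in kinematics engine.
- Planning operates on the static planning scan; organ motion or
  deformation between planning and execution is out of scope.
- The relative-objective distribution depends strongly on body shape; values
  from ellipsoidal phantoms do not transfer to patient anatomy.
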