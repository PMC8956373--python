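# needleplan

Planning and decision support for CT-guided robotic needle biopsy.

Given a CT volume and an annotated target point, `needleplan` segments the
skin, classifies every point of the skin surface by whether a needle could be
inserted there — needle range, occlusion by other body parts, dense
structures (bone, implants) on the path with a safety margin, insertion
angle, and robot reachability — and suggests the entry point with the lowest
cost. Around that core it provides the machinery a robotic biopsy system
needs: QR24 hand-eye calibration of the robot/camera pair, CT-to-robot
registration from a steel-ball fiducial phantom, and placement-accuracy
evaluation of executed insertions. It is aimed at researchers building or
simulating image-guided intervention systems; everything runs on synthetic
CT phantoms with known ground truth, so no scan data is required.

## The planning model

For a target **t** and a skin vertex **p** with outward normal **n**, the
insertion depth is *d* = ‖**p** − **t**‖ and the insertion angle *a* is the
angle between the insertion direction and the inward normal −**n**. Feasible
vertices are scored with

    q = 0.5 · (d / l) + 0.5 · (a / 90°)

where *l* is the effective needle length (160 mm for a 190 mm guide needle in
its holder). The planner walks the steps in order, each restricting the
previous set:

1. **Range** — discard vertices with *d* ≥ *l*.
2. **Occlusion** — discard vertices whose outward ray is blocked by another
   body part (e.g. an arm) within the instrument clearance.
3. **Maximum HU projection** — compute the maximum Hounsfield value along
   the target→vertex segment (trilinear interpolation with adaptive
   branch-and-bound refinement); discard vertices above the dense-structure
   threshold (default 300 HU).
4. **Safety margin** — discard vertices within 5 mm (Euclidean) of any
   dense-blocked vertex.
5. **Angle** — discard grazing insertions (*a* ≥ 90°).
6. **Reachability** — query a pluggable robot-reachability oracle on a
   coarse surface grid (default 30 mm cells); a geometric default models a
   reach annulus, an approach corridor, and the CT gantry plane.

The minimum-*q* survivor is the suggested entry. Calibration solves
B·X·C = Y for the end-effector→marker and base→camera transforms by
unconstrained linear least squares over all 24 matrix parameters (QR24),
then projects the rotations onto the nearest proper rotations. CT
registration detects the 24 steel balls (radii 2 and 5 mm) of a registration
phantom, matches them to CAD coordinates by pairwise-distance fingerprints,
fits a rigid transform, and composes
base→CT = (base→camera)(camera→marker)(marker→balls)(balls→CT).
Placement accuracy is the distance from the annotated target to the biopsy
center (10 mm beyond the detected needle tip), split into lateral and axial
components.

## Worked example

`examples/plan_insertion.py` plans an insertion to a target shielded by rib
arcs on a synthetic torso:

```
skin mesh: 22568 vertices, 608 cm^2
vertex categories: {'DENSE_BLOCKED': 3368, 'MARGIN_BLOCKED': 2972, 'FEASIBLE': 16228}
feasible area: 412 cm^2
optimal entry [ 96. 149.  96.] mm
  depth 54.0 mm, angle 1.5 deg, cost 0.177
```

The rib arcs block 3368 skin vertices outright and the 5 mm safety margin
removes another 2972 around them; the chosen entry goes straight through the
anterior intercostal gap — 54 mm deep, 1.5° off perpendicular, cost 0.177 on
the 0–1 scale (0 would be a zero-depth perpendicular insertion). The other
examples cover calibration (`calibrate_hand_eye.py`), registration
(`register_ct.py`), and placement evaluation (`evaluate_placements.py`).
A thin CLI wraps the same pipeline (`needleplan phantom/segment/plan/
calibrate/evaluate`; exit code 2 signals "no feasible path").

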