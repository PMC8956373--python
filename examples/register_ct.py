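"""Register a CT scan into the robot base frame via steel-ball fiducials.

Rasterizes the 24-ball registration phantom (two radius classes, 2 and 5 mm)
under a random pose into a CT volume, detects the ball centroids by
thresholding, matches them to the CAD grid by pairwise-distance
fingerprints, fits the rigid transform, and composes the calibration chain
base->camera->marker->balls->CT. The recovery error against the generator's
ground truth is the end-to-end registration accuracy of the pipeline.
"""

import numpy as np

import needleplan as npl

rng = np.random.default_rng(7)
fiducials = npl.make_fiducial_set(seed=7, spacing=0.6)
detected = npl.detect_fiducials(fiducials.volume, threshold=1500.0)
print(f"detected {len(detected)} steel balls in a "
      f"{'x'.join(map(str, fiducials.volume.shape))} scan at 0.6 mm")

# tracked phantom pose and CAD link, as a camera would supply them
marker_from_balls = npl.RigidTransform.random(rng, max_translation=40.0)
base_from_camera = npl.RigidTransform.random(rng, max_translation=700.0)
camera_from_marker = npl.RigidTransform.random(rng, max_translation=400.0)

estimate, rmse = npl.register_ct_to_base(
    detected, (fiducials.cad_centers, fiducials.radii),
    base_from_camera, camera_from_marker, marker_from_balls,
)
truth = npl.compose_chain([base_from_camera, camera_from_marker,
                           marker_from_balls, fiducials.ct_from_sb.inverse()])
print(f"fiducial fit RMSE: {rmse:.3f} mm")
print(f"base->CT recovery error: {estimate.translation_distance_to(truth):.4f} mm, "
      f"{estimate.rotation_angle_to(truth):.5f} deg")
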