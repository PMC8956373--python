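"""Shared fixtures: small phantoms with segmentations, reused across modules.

Phantoms are 64^3 at 3 mm spacing — coarse enough to keep the suite fast,
fine enough that voxel-scale tolerances (half a voxel, mesh-normal
discretization) stay meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from needleplan import extract_surface, make_phantom, segment_body, study_specs
from needleplan.phantom import PhantomData
from needleplan.segmentation import BodyMask, SurfaceMesh


@pytest.fixture(scope="session")
def specs():
    return study_specs(n=64, spacing=3.0)


def _segmented(ph: PhantomData) -> tuple[PhantomData, BodyMask, SurfaceMesh]:
    mask = segment_body(ph.volume)
    return ph, mask, extract_surface(mask)


@pytest.fixture(scope="session")
def sphere_case(specs):
    return _segmented(make_phantom(specs["sphere"]))


@pytest.fixture(scope="session")
def torso_case(specs):
    return _segmented(make_phantom(specs["torso_lungs"]))


@pytest.fixture(scope="session")
def rib_case(specs):
    return _segmented(make_phantom(specs["rib_cage"]))


@pytest.fixture(scope="session")
def arm_case(specs):
    ph = make_phantom(specs["arm"])
    mask = segment_body(ph.volume)  # largest component: torso without the arm
    mesh = extract_surface(mask)
    # occlusion needs the arm in the obstacle mask; build it from ground truth
    full = BodyMask(
        mask=ph.structures["body_with_arm"],
        spacing=ph.volume.spacing,
        origin=ph.volume.origin,
        direction=ph.volume.direction,
        threshold=-300.0,
        closing_radius=0.0,
    )
    return ph, mask, mesh, full


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
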