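"""Rigid 4x4 homogeneous transforms.

All frames in this package are metric (millimetres). A :class:`RigidTransform`
maps points of its *source* frame into its *destination* frame; composition is
plain matrix multiplication, so ``T_ab @ T_bc`` maps frame ``c`` into frame
``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


class TransformError(ValueError):
    """Raised when a matrix is not a valid rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: orthonormal rotation (det +1) + translation."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise TransformError(f"expected 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
            raise TransformError("last row must be (0, 0, 0, 1)")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise TransformError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise TransformError("rotation block must have det +1")
        object.__setattr__(self, "matrix", m)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_translation(cls, translation: np.ndarray) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), translation)

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 100.0) -> "RigidTransform":
        """Uniform random rotation with translation in a cube of half-width
        ``max_translation`` mm."""
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls.from_rotation_translation(rot, t)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra -----------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point or an (n, 3) array of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    # -- metrics -----------------------------------------------------------
    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Geodesic rotation distance in degrees: angle of R_self R_other^T."""
        rel = self.rotation @ other.rotation.T
        return float(np.degrees(Rotation.from_matrix(rel).magnitude()))

    def translation_distance_to(self, other: "RigidTransform") -> float:
        return float(np.linalg.norm(self.translation - other.translation))


def nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Orthogonal polar factor of ``m`` with det forced to +1.

    This is the Frobenius-nearest proper rotation to an arbitrary 3x3 matrix.
    """
    u, _, vt = np.linalg.svd(np.asarray(m, dtype=float))
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt
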