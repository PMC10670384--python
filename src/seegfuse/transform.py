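"""Rigid (and affine) spatial transforms acting on world-mm points.

Convention (documented once, used everywhere): a transform maps *fixed*-image
world points into *moving*-image space, the standard resampling convention of
ITK-family toolkits.  Registration results therefore resample the moving MRI
onto the CT grid directly, and fiducial evaluation maps CT-space points
through the same object.

The action on a point is ``p' = M @ (p - center) + center + translation``
where ``M`` is the 3x3 linear part (a rotation for rigid transforms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import ContractError

__all__ = ["RigidTransform"]


@dataclass
class RigidTransform:
    """Rotation + translation about a center, in world mm.

    ``matrix`` may be a general invertible linear map when produced by the
    affine registration mode; :meth:`is_rigid` reports whether it is a pure
    rotation.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ContractError("transform matrix is singular")

    # --- constructors -----------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(translation=np.asarray(t, dtype=float))

    @classmethod
    def from_euler(cls, angles_rad, translation=(0, 0, 0), center=(0, 0, 0)) -> "RigidTransform":
        """Rotation from extrinsic x-y-z Euler angles (radians)."""
        ax, ay, az = angles_rad
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(matrix=rz @ ry @ rx, translation=np.asarray(translation, float),
                   center=np.asarray(center, float))

    # --- algebra ----------------------------------------------------------

    def is_rigid(self, atol: float = 1e-6) -> bool:
        m = self.matrix
        return bool(np.allclose(m @ m.T, np.eye(3), atol=atol) and np.linalg.det(m) > 0)

    def apply(self, points) -> np.ndarray:
        """Map one (3,) point or an (N,3) array of world-mm points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = (p - self.center) @ self.matrix.T + self.center + self.translation
        return out[0] if single else out

    def __call__(self, points) -> np.ndarray:
        return self.apply(points)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        # Rewrite both to offset form p' = M p + b, then combine.
        m1, b1 = self._matrix_offset()
        m2, b2 = other._matrix_offset()
        return RigidTransform(matrix=m1 @ m2, translation=m1 @ b2 + b1, center=np.zeros(3))

    def inverse(self) -> "RigidTransform":
        m, b = self._matrix_offset()
        mi = np.linalg.inv(m)
        return RigidTransform(matrix=mi, translation=-mi @ b, center=np.zeros(3))

    def _matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        """(M, b) with p' = M p + b (center folded into the offset)."""
        b = self.center + self.translation - self.matrix @ self.center
        return self.matrix, b

    def as_matrix4(self) -> np.ndarray:
        m, b = self._matrix_offset()
        out = np.eye(4)
        out[:3, :3] = m
        out[:3, 3] = b
        return out

    # --- SimpleITK bridge -------------------------------------------------

    def to_sitk(self) -> sitk.Transform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.matrix.ravel()))
        t.SetTranslation(tuple(self.translation))
        t.SetCenter(tuple(self.center))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform":
        t = t.Downcast() if hasattr(t, "Downcast") else t
        if isinstance(t, sitk.CompositeTransform):
            if t.GetNumberOfTransforms() != 1:
                t.FlattenTransform()
            if t.GetNumberOfTransforms() != 1:
                raise ContractError("cannot convert a multi-component composite transform")
            t = t.GetNthTransform(0)
            t = t.Downcast() if hasattr(t, "Downcast") else t
        params_matrix = np.asarray(t.GetMatrix()).reshape(3, 3)
        return cls(matrix=params_matrix,
                   translation=np.asarray(t.GetTranslation()),
                   center=np.asarray(t.GetCenter()))

    # --- plain-text serialization ------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as a plain-text 4x4 homogeneous matrix plus center (mm)."""
        lines = ["# seegfuse rigid transform: 4x4 world-mm matrix, then center"]
        lines += [" ".join(f"{x:.12g}" for x in row) for row in self.as_matrix4()]
        lines.append(" ".join(f"{x:.12g}" for x in self.center))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        rows = [
            [float(x) for x in ln.split()]
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        mat4 = np.asarray(rows[:4])
        center = np.asarray(rows[4])
        m = mat4[:3, :3]
        b = mat4[:3, 3]
        # Recover a centered representation: translation = b - center + M center
        return cls(matrix=m, translation=b - center + m @ center, center=center)

    def max_deviation_from(self, other: "RigidTransform", points) -> float:
        """Largest displacement (mm) between the two maps over given points."""
        return float(np.max(np.linalg.norm(self.apply(points) - other.apply(points), axis=1)))
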