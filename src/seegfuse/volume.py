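"""3-D volumes and binary masks with an explicit world-coordinate model.

A :class:`Volume` is a scalar grid plus the geometry needed to map voxel
indices to physical millimetres: ``spacing`` (mm per voxel along each axis),
``origin`` (world position of the *center* of voxel ``(0, 0, 0)``) and a 3x3
orthonormal ``direction`` matrix of axis cosines.  All transforms and
fiducial points in this package live in world mm, never in voxel indices.
Arrays are indexed ``data[i, j, k]`` with axis order matching the geometry
(the NIfTI-native frame); no axis flipping is performed on I/O.

The world position of voxel index ``v`` is ``origin + direction @ (v * spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import ContractError, GeometryError
from .transform import RigidTransform

__all__ = ["Volume", "BinaryMask", "read_volume", "write_volume", "resample_volume"]

_GEOM_ATOL = 1e-5


@dataclass
class Volume:
    """Scalar 3-D image (CT in Hounsfield units, MRI in arbitrary units)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ContractError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        d = self.direction
        if d.shape != (3, 3) or not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise GeometryError(f"direction matrix is not orthonormal:\n{d}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """World-space span between first and last voxel centers per axis."""
        return tuple((n - 1) * s for n, s in zip(self.dims, self.spacing))

    def same_geometry(self, other: "Volume") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_ATOL)
            and np.allclose(self.origin, other.origin, atol=_GEOM_ATOL)
            and np.allclose(self.direction, other.direction, atol=_GEOM_ATOL)
        )

    def index_to_world(self, index) -> np.ndarray:
        """World mm of one voxel index (or an (N,3) array of indices)."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction.T
        return pts[0] if np.ndim(index) == 1 else pts

    def world_grid(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates."""
        axes = [np.arange(n) * s for n, s in zip(self.dims, self.spacing)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return np.asarray(self.origin) + grid @ self.direction.T

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on this grid carrying ``data``."""
        return replace(self, data=np.asarray(data))

    # --- SimpleITK bridge (array axis order is reversed: sitk is (z,y,x)) ---

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            data=arr,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )


class BinaryMask(Volume):
    """A {0,1} grid sharing its parent Volume's geometry exactly.

    Used for electrode, skull, head, brain and registration sampling masks.
    """

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ContractError(f"mask values must be 0/1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        super().__post_init__()

    @classmethod
    def like(cls, parent: Volume, data: np.ndarray) -> "BinaryMask":
        if data.shape != parent.dims:
            raise GeometryError(f"mask shape {data.shape} != parent dims {parent.dims}")
        return cls(data=data, spacing=parent.spacing, origin=parent.origin,
                   direction=parent.direction.copy())

    def complement(self) -> "BinaryMask":
        return BinaryMask.like(self, 1 - self.data)

    @property
    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


def read_volume(path: str | Path, *, mask: bool = False) -> Volume:
    """Read a NIfTI volume (.nii / .nii.gz).

    Intensities are returned exactly as stored apart from the format's own
    slope/intercept scaling.  ``mask=True`` validates and returns a
    :class:`BinaryMask` instead.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps parse failures in RuntimeError
        raise IOError(f"could not read {path}: {exc}") from exc
    v = Volume.from_sitk(img)
    return BinaryMask.like(v, v.data) if mask else v


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI; masks go out as unsigned 8-bit, CT keeps sign."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = v.data
    if isinstance(v, BinaryMask):
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16 if data.min() < 0 or data.max() < 2**15 else np.int32)
    else:
        data = data.astype(np.float32)
    sitk.WriteImage(v.with_data(data).to_sitk(), str(path))


_INTERPOLATORS = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear}


def resample_volume(
    moving: Volume,
    reference: Volume,
    t: RigidTransform | None = None,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> Volume:
    """Resample ``moving`` onto ``reference``'s grid under transform ``t``.

    ``t`` maps reference-space world points into moving space (the resampling
    convention); ``None`` means identity.  Voxels that map outside ``moving``
    take ``fill`` (use -1000 for CT so the exterior reads as air).  Binary
    masks must use nearest-neighbour interpolation and return a BinaryMask.
    """
    if interpolation not in _INTERPOLATORS:
        raise ContractError(f"interpolation must be one of {sorted(_INTERPOLATORS)}")
    is_mask = isinstance(moving, BinaryMask)
    if is_mask and interpolation != "nearest":
        raise ContractError("binary masks must be resampled with nearest interpolation")
    t = t if t is not None else RigidTransform.identity()
    out = sitk.Resample(
        moving.to_sitk(),
        reference.to_sitk(),
        t.to_sitk(),
        _INTERPOLATORS[interpolation],
        float(fill),
    )
    result = Volume.from_sitk(out)
    if is_mask:
        return BinaryMask.like(reference, result.data)
    return result.with_data(result.data.astype(moving.data.dtype, copy=False))
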