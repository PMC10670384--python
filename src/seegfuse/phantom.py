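"""Synthetic head phantoms with implanted SEEG electrode cylinders.

The generator produces a co-registered CT/MRI pair of an ellipsoidal head
— scalp, skull shell, brain interior, two off-center ventricle-like
structures that break mirror symmetry — plus a ground-truth brain mask and
the eight field-of-view corner fiducials.  Electrodes are rigid cylinders
(default: 12 of them, 3 mm diameter, 80 mm long, per-voxel intensities
uniform in 1500-3000 HU) implanted at random poses fully inside the brain,
mirroring commercial depth electrodes with eight contacts at 10 mm pitch.

Every output is bit-reproducible per seed.  Known misalignments
(:func:`perturb_moving`) and focal tissue variations
(:func:`add_tissue_variation`) let the masked-vs-unmasked registration
comparison run without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ContractError, PlacementError
from .metrics import FiducialSet
from .transform import RigidTransform
from .volume import BinaryMask, Volume, resample_volume

__all__ = [
    "ElectrodeSpec",
    "PhantomConfig",
    "HeadPhantom",
    "Trajectory",
    "make_head_phantom",
    "insert_electrodes",
    "add_tissue_variation",
    "trajectory_variation_regions",
    "perturb_moving",
    "corner_fiducials",
]

# label codes used by the generator
AIR, SCALP, SKULL, BRAIN, VENTRICLE = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class ElectrodeSpec:
    """Geometry and intensity of simulated depth electrodes."""

    diameter_mm: float = 3.0
    length_mm: float = 80.0
    n_contacts: int = 8
    contact_spacing_mm: float = 10.0
    hu_range: tuple[float, float] = (1500.0, 3000.0)
    count: int = 12
    intensity: str | float = "uniform"  # 'uniform' per voxel, or a constant HU

    def __post_init__(self) -> None:
        if min(self.diameter_mm, self.length_mm, self.contact_spacing_mm) <= 0:
            raise ContractError("electrode dimensions must be positive")
        if self.count < 0:
            raise ContractError("electrode count must be >= 0")
        if (self.n_contacts - 1) * self.contact_spacing_mm > self.length_mm:
            raise ContractError("contacts do not fit on the electrode shaft")


@dataclass(frozen=True)
class PhantomConfig:
    """Head phantom geometry, tissue intensities and noise.

    CT values are Hounsfield units (air -1000, soft tissue ~40, cortical
    bone in a 400-1400 band); MRI values are arbitrary T1-like units.
    """

    dims: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    head_semiaxes_mm: tuple[float, float, float] = (70.0, 85.0, 75.0)
    scalp_thickness_mm: float = 5.0
    skull_thickness_mm: float = 6.0
    ct_values: dict = field(default_factory=lambda: {
        "air": -1000.0, "scalp": 40.0, "skull_lo": 400.0, "skull_hi": 1400.0,
        "brain": 40.0, "ventricle": 10.0,
    })
    mri_values: dict = field(default_factory=lambda: {
        "air": 0.0, "scalp": 300.0, "skull": 80.0, "brain": 500.0, "ventricle": 900.0,
    })
    # smooth intensity lumps inside the MRI brain: real brain tissue is
    # heterogeneous, and a uniform interior would make electrode voxels
    # uninformative for the registration metric
    mri_texture_amp: float = 80.0
    mri_texture_count: int = 40
    mri_texture_radius_mm: float = 18.0
    ct_noise_sd: float = 10.0
    mri_noise_sd: float = 15.0
    seed: int = 0


class Trajectory(NamedTuple):
    """One implanted electrode axis: entry point, unit direction, length (mm)."""

    entry: np.ndarray
    direction: np.ndarray
    length_mm: float

    @property
    def tip(self) -> np.ndarray:
        return self.entry + self.length_mm * self.direction

    @property
    def midpoint(self) -> np.ndarray:
        return self.entry + 0.5 * self.length_mm * self.direction


@dataclass
class HeadPhantom:
    ct: Volume
    mri: Volume
    brain_mask: BinaryMask
    fiducials: FiducialSet
    labels: np.ndarray          # tissue label codes, pre-noise ground truth
    ct_noiseless: np.ndarray    # CT before Gaussian noise (generator self-checks)


def _ellipsoid_rho(cfg: PhantomConfig, semiaxes) -> np.ndarray:
    """Normalised ellipsoid radius at every voxel center (identity frame)."""
    axes = [np.arange(n) * s for n, s in zip(cfg.dims, cfg.spacing)]
    center = [0.5 * (n - 1) * s for n, s in zip(cfg.dims, cfg.spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    a, b, c = semiaxes
    cx, cy, cz = center
    return np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 + ((zz - cz) / c) ** 2)


def make_head_phantom(cfg: PhantomConfig | None = None) -> HeadPhantom:
    """Build the co-registered CT/MRI pair with ground truth.

    The head is an ellipsoid nested as scalp / skull shell / brain, with two
    asymmetric ventricle-like inclusions.  Raises if the head does not fit
    inside the grid with a 2-voxel margin.
    """
    cfg = cfg or PhantomConfig()
    extent = [(n - 1) * s for n, s in zip(cfg.dims, cfg.spacing)]
    for ax, (a, e, s) in enumerate(zip(cfg.head_semiaxes_mm, extent, cfg.spacing)):
        if 2 * a > e - 4 * s:
            raise ContractError(f"head semi-axis {a} mm does not fit grid axis {ax} "
                                f"({e:.1f} mm) with margin")

    outer = cfg.head_semiaxes_mm
    skull_out = tuple(a - cfg.scalp_thickness_mm for a in outer)
    skull_in = tuple(a - cfg.skull_thickness_mm for a in skull_out)

    labels = np.full(cfg.dims, AIR, dtype=np.uint8)
    labels[_ellipsoid_rho(cfg, outer) <= 1.0] = SCALP
    labels[_ellipsoid_rho(cfg, skull_out) <= 1.0] = SKULL
    labels[_ellipsoid_rho(cfg, skull_in) <= 1.0] = BRAIN

    # two off-center ventricle-like spheres; asymmetric to pin orientation
    center = np.array([0.5 * e for e in extent])
    axes = [np.arange(n) * s for n, s in zip(cfg.dims, cfg.spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    for offset, radius in (((12.0, 9.0, 6.0), 12.0), ((-16.0, -12.0, -9.0), 9.0)):
        c = center + np.asarray(offset)
        sphere = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= radius**2
        labels[sphere & (labels == BRAIN)] = VENTRICLE

    rng = np.random.default_rng(cfg.seed)
    cv, mv = cfg.ct_values, cfg.mri_values
    ct = np.full(cfg.dims, cv["air"], dtype=np.float32)
    ct[labels == SCALP] = cv["scalp"]
    n_skull = int((labels == SKULL).sum())
    ct[labels == SKULL] = rng.uniform(cv["skull_lo"], cv["skull_hi"], n_skull)
    ct[labels == BRAIN] = cv["brain"]
    ct[labels == VENTRICLE] = cv["ventricle"]
    ct_noiseless = ct.copy()

    mri = np.full(cfg.dims, mv["air"], dtype=np.float32)
    for code, key in ((SCALP, "scalp"), (SKULL, "skull"), (BRAIN, "brain"), (VENTRICLE, "ventricle")):
        mri[labels == code] = mv[key]

    brain_region = (labels == BRAIN) | (labels == VENTRICLE)
    if cfg.mri_texture_amp > 0 and cfg.mri_texture_count > 0:
        brain_idx = np.argwhere(brain_region)
        for _ in range(cfg.mri_texture_count):
            c = brain_idx[rng.integers(len(brain_idx))] * np.asarray(cfg.spacing)
            d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
            lump = rng.uniform(-cfg.mri_texture_amp, cfg.mri_texture_amp)
            mri += (lump * np.exp(-d2 / (2 * cfg.mri_texture_radius_mm**2)) * brain_region
                    ).astype(np.float32)

    ct += rng.normal(0.0, cfg.ct_noise_sd, cfg.dims).astype(np.float32)
    mri += rng.normal(0.0, cfg.mri_noise_sd, cfg.dims).astype(np.float32)

    geom = dict(spacing=cfg.spacing, origin=(0.0, 0.0, 0.0), direction=np.eye(3))
    ct_vol = Volume(ct, **geom)
    mri_vol = Volume(mri, **geom)
    brain = BinaryMask.like(ct_vol, brain_region.astype(np.uint8))
    fiducials = corner_fiducials(tuple(extent))
    return HeadPhantom(ct_vol, mri_vol, brain, fiducials, labels, ct_noiseless)


# --------------------------------------------------------------------------
# electrode insertion


def _segment_distance(p0, d0, l0, p1, d1, l1) -> float:
    """Minimum distance between two 3-D segments (clamped closest points)."""
    # Standard closest-point parameterisation; robust to parallel segments.
    r = p0 - p1
    a = l0 * l0
    e = l1 * l1
    f = np.dot(d1 * l1, r)
    c = np.dot(d0 * l0, r)
    b = np.dot(d0 * l0, d1 * l1)
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
    elif t > 1.0:
        t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    c0 = p0 + s * l0 * d0
    c1 = p1 + t * l1 * d1
    return float(np.linalg.norm(c0 - c1))


def _world_to_index(vol: Volume, pts: np.ndarray) -> np.ndarray:
    rel = (np.atleast_2d(pts) - np.asarray(vol.origin)) @ vol.direction
    return rel / np.asarray(vol.spacing)


def insert_electrodes(
    ct: Volume,
    brain_mask: BinaryMask,
    spec: ElectrodeSpec | None = None,
    seed: int = 0,
    max_tries_per_electrode: int = 2000,
) -> tuple[Volume, BinaryMask, list[Trajectory]]:
    """Implant ``spec.count`` cylinders at random poses inside the brain.

    Each cylinder (flat caps) is voxelised exactly into both the returned CT
    and the ground-truth mask; axes are kept fully inside the brain mask and
    pairwise separated so the voxelised electrodes never touch, keeping
    26-connected component counts equal to ``spec.count``.  Raises
    :class:`PlacementError` (with the achieved count) if placement fails.
    """
    spec = spec or ElectrodeSpec()
    if spec.count > 0 and not brain_mask.data.any():
        raise ContractError("brain mask is empty; nowhere to place electrodes")
    rng = np.random.default_rng(seed)
    radius = spec.diameter_mm / 2.0
    spacing = np.asarray(ct.spacing)
    # erode brain so the whole cylinder (axis + radius + margin) stays inside
    margin_vox = int(np.ceil((radius + max(spacing)) / min(spacing)))
    ball = ndimage.generate_binary_structure(3, 1)
    allowed = ndimage.binary_erosion(brain_mask.as_bool, structure=ball,
                                     iterations=max(margin_vox, 1))
    allowed_idx = np.argwhere(allowed)
    if spec.count > 0 and len(allowed_idx) == 0:
        raise ContractError("brain mask too thin for the requested electrode radius")

    # Two truth voxels from different cylinders can only be 26-adjacent if the
    # axes come within diameter + one voxel diagonal; add 1 mm of slack.
    min_gap = spec.diameter_mm + float(max(spacing)) * np.sqrt(3.0) + 1.0
    placed: list[Trajectory] = []
    truth = np.zeros(ct.dims, dtype=np.uint8)
    ct_out = ct.data.astype(np.float32).copy()

    n_axis_samples = max(int(spec.length_mm / min(spacing)) * 2, 8)
    ts = np.linspace(0.0, 1.0, n_axis_samples)

    for k in range(spec.count):
        for _ in range(max_tries_per_electrode):
            mid_idx = allowed_idx[rng.integers(len(allowed_idx))]
            mid = ct.index_to_world(mid_idx.astype(float))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            entry = mid - 0.5 * spec.length_mm * d
            # axis entirely inside the eroded brain?
            pts = entry + ts[:, None] * spec.length_mm * d
            idx = np.rint(_world_to_index(ct, pts)).astype(int)
            if (idx < 0).any() or (idx >= np.asarray(ct.dims)).any():
                continue
            if not allowed[idx[:, 0], idx[:, 1], idx[:, 2]].all():
                continue
            if any(
                _segment_distance(entry, d, spec.length_mm, t.entry, t.direction, t.length_mm) < min_gap
                for t in placed
            ):
                continue
            _voxelize_cylinder(ct_out, truth, ct, entry, d, spec, rng)
            placed.append(Trajectory(entry, d, spec.length_mm))
            break
        else:
            raise PlacementError(
                f"placed only {len(placed)}/{spec.count} electrodes", achieved=len(placed)
            )
    return ct.with_data(ct_out), BinaryMask.like(ct, truth), placed


def _voxelize_cylinder(ct_out, truth, vol: Volume, entry, d, spec: ElectrodeSpec, rng) -> None:
    """Exact flat-capped cylinder voxelisation inside a bounding box."""
    radius = spec.diameter_mm / 2.0
    ends = np.stack([entry, entry + spec.length_mm * d])
    idx_ends = _world_to_index(vol, ends)
    pad = radius / min(vol.spacing) + 2
    lo = np.maximum(np.floor(idx_ends.min(axis=0) - pad).astype(int), 0)
    hi = np.minimum(np.ceil(idx_ends.max(axis=0) + pad).astype(int) + 1, np.asarray(vol.dims))
    sub_axes = [np.arange(lo[i], hi[i]) * vol.spacing[i] for i in range(3)]
    xx, yy, zz = np.meshgrid(*sub_axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1) + np.asarray(vol.origin)
    rel = pts - entry
    t = rel @ d
    perp2 = np.einsum("...i,...i", rel, rel) - t**2
    inside = (t >= 0.0) & (t <= spec.length_mm) & (perp2 <= radius**2)
    n_in = int(inside.sum())
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    if spec.intensity == "uniform":
        values = rng.uniform(spec.hu_range[0], spec.hu_range[1], n_in)
    else:
        values = np.full(n_in, float(spec.intensity))
    region = ct_out[sl]
    region[inside] = values
    ct_out[sl] = region
    tr = truth[sl]
    tr[inside] = 1
    truth[sl] = tr


# --------------------------------------------------------------------------
# tissue variation, misalignment, fiducials


def add_tissue_variation(v: Volume, regions) -> Volume:
    """Additive spherical intensity offsets: regions are (center_mm, radius_mm, delta)."""
    if not regions:
        return v.with_data(v.data.copy())
    out = v.data.astype(np.float32).copy()
    axes = [np.arange(n) * s for n, s in zip(v.dims, v.spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    xx, yy, zz = (g + o for g, o in zip((xx, yy, zz), v.origin))
    for center, radius, delta in regions:
        c = np.asarray(center, dtype=float)
        sphere = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= radius**2
        out[sphere] += delta
    return v.with_data(out)


def trajectory_variation_regions(
    trajectories: list[Trajectory],
    n: int = 6,
    radius_mm: float = 6.0,
    delta: float = -400.0,
    offset_mm: float = 5.0,
    n_spheres: int = 9,
    span: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> list[tuple[np.ndarray, float, float]]:
    """Tissue-variation tubes along electrode tracks, offset a few mm sideways.

    Emulates brain tissue that changed between the MRI and CT acquisitions
    (pathology evolution, implantation-induced edema, small brain shift) in
    areas the electrodes traverse.  Each affected trajectory gets a chain of
    ``n_spheres`` spheres over the middle ``span`` of its length, displaced
    ``offset_mm`` along a random perpendicular so the inconsistent tissue
    forms coherent structure *near* — not exactly on — the metal track.
    Masked registration samples none of the electrode voxels crossing these
    areas; unmasked registration does, and is pulled by them.
    """
    rng = np.random.default_rng(seed)
    regions: list[tuple[np.ndarray, float, float]] = []
    for t in trajectories[:n]:
        if offset_mm:
            perp = np.cross(t.direction, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
        else:
            perp = np.zeros(3)
        for s in np.linspace(span[0], span[1], n_spheres):
            center = t.entry + s * t.length_mm * t.direction + offset_mm * perp
            regions.append((center, radius_mm, delta))
    return regions


def perturb_moving(mri: Volume, t: RigidTransform, fill: float = 0.0) -> Volume:
    """Resample the MRI under ``t`` onto its own grid (known misalignment).

    The perturbed image satisfies ``out(x) = mri(t(x))``, so a registration
    of ``out`` against the original fixed image should recover
    ``t.inverse()`` as its fixed-to-moving transform.
    """
    return resample_volume(mri, mri, t, interpolation="linear", fill=fill)


def corner_fiducials(extent) -> FiducialSet:
    """The 8 corner points of a (X, Y, Z) mm extent, in standard order.

    Order: (0,0,0), (X,0,0), (0,Y,0), (X,Y,0), then the same square at Z.
    """
    x, y, z = (float(e) for e in extent)
    if min(x, y, z) <= 0:
        raise ContractError("extents must be positive")
    pts = [
        (0, 0, 0), (x, 0, 0), (0, y, 0), (x, y, 0),
        (0, 0, z), (x, 0, z), (0, y, z), (x, y, z),
    ]
    return FiducialSet.from_arrays([str(i + 1) for i in range(8)], np.asarray(pts, dtype=float))
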