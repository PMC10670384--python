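"""CT electrode segmentation by HU thresholding and 3-D morphology.

Implanted SEEG electrodes are metallic and sit in a narrow high-HU band
(1500-3000 HU) that overlaps the upper end of cortical bone (300-1900 HU).
A plain threshold therefore catches electrodes *and* skull.  The pipeline
removes the skull with mask algebra:

1. threshold electrodes in [1500, 3000] HU;
2. threshold skull in [300, 1900] HU, erode with a 3x3x3 cross kernel to
   knock out the thin electrode tracks, then close and dilate with a ball
   kernel to reconnect bone -> skull mask;
3. NOT skull -> no-skull mask;
4. Otsu threshold + hole filling -> head mask (drops the frame, pillow, air);
5. head AND no-skull -> brain-region mask;
6. electrodes AND brain-region -> initial electrode mask.

The complement of the electrode mask is the registration sampling mask; a
brain mask from the registered MRI later removes residual bone fragments
(:func:`refine_electrodes`).  Threshold windows are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ContractError, GeometryError
from .volume import BinaryMask, Volume

__all__ = [
    "HUWindow",
    "StructuringElement",
    "ELECTRODE_WINDOW",
    "SKULL_WINDOW",
    "threshold_range",
    "make_skull_mask",
    "make_no_skull_mask",
    "make_head_mask",
    "make_brain_region_mask",
    "segment_electrodes_initial",
    "make_sampling_mask",
    "refine_electrodes",
    "count_components",
]


@dataclass(frozen=True)
class HUWindow:
    """Closed Hounsfield-unit interval [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ContractError(f"HU window lower bound {self.lo} exceeds upper {self.hi}")


ELECTRODE_WINDOW = HUWindow(1500.0, 3000.0)
SKULL_WINDOW = HUWindow(300.0, 1900.0)


@dataclass(frozen=True)
class StructuringElement:
    """Morphological kernel: 6-connected cross or discrete Euclidean ball.

    A "ball of size 4" (even extent, no center voxel) is realised as the
    discrete ball of radius ``size // 2`` voxels, the closest odd-sized
    approximation.
    """

    shape: str = "cross"
    size: int = 3

    def __post_init__(self) -> None:
        if self.shape not in ("cross", "ball"):
            raise ContractError(f"unknown structuring element shape {self.shape!r}")
        if self.size < 1:
            raise ContractError("structuring element size must be >= 1")

    def footprint(self) -> np.ndarray:
        if self.shape == "cross":
            return ndimage.generate_binary_structure(3, 1)  # 7-voxel 6-connected cross
        r = self.size // 2
        n = 2 * r + 1
        zz, yy, xx = np.mgrid[:n, :n, :n] - r
        return (xx**2 + yy**2 + zz**2) <= r**2


def threshold_range(v: Volume, w: HUWindow) -> BinaryMask:
    """Binary mask of voxels with ``w.lo <= value <= w.hi`` (inclusive)."""
    return BinaryMask.like(v, ((v.data >= w.lo) & (v.data <= w.hi)).astype(np.uint8))


def make_skull_mask(
    ct: Volume,
    window: HUWindow = SKULL_WINDOW,
    cross: StructuringElement = StructuringElement("cross", 3),
    ball: StructuringElement = StructuringElement("ball", 4),
) -> BinaryMask:
    """Skull mask: threshold -> erode(cross 3^3) -> close(ball) -> dilate(ball).

    The erosion eliminates the thin electrode tracks that fall inside the
    bone window; closing + dilation reconnect and thicken the bone shell.
    """
    m = threshold_range(ct, window).as_bool
    m = ndimage.binary_erosion(m, structure=cross.footprint())
    fp = ball.footprint()
    m = ndimage.binary_closing(m, structure=fp)
    m = ndimage.binary_dilation(m, structure=fp)
    return BinaryMask.like(ct, m.astype(np.uint8))


def make_no_skull_mask(skull: BinaryMask) -> BinaryMask:
    """Voxelwise complement of the skull mask."""
    return skull.complement()


def make_head_mask(ct: Volume) -> BinaryMask:
    """Head mask by Otsu thresholding, then 3-D hole filling.

    Hole filling complements the background component reachable from the
    array border (6-connectivity), so interior air cavities become head.
    """
    data = ct.data
    if np.min(data) == np.max(data):
        raise ContractError("Otsu threshold undefined for a constant image")
    thr = threshold_otsu(np.asarray(data, dtype=float))
    head = data > thr
    filled = _fill_holes_3d(head)
    return BinaryMask.like(ct, filled.astype(np.uint8))


def _fill_holes_3d(mask: np.ndarray) -> np.ndarray:
    """Fill cavities not connected to the border under 6-connectivity."""
    bg = ~mask
    labels, _ = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
    border_labels = np.unique(
        np.concatenate([
            labels[0].ravel(), labels[-1].ravel(),
            labels[:, 0].ravel(), labels[:, -1].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
        ])
    )
    outside = np.isin(labels, border_labels[border_labels > 0])
    return ~(bg & outside)


def make_brain_region_mask(head: BinaryMask, no_skull: BinaryMask) -> BinaryMask:
    """Intersection of the head mask and the no-skull mask."""
    if not head.same_geometry(no_skull):
        raise GeometryError("head and no-skull masks are on different grids")
    return BinaryMask.like(head, head.data & no_skull.data)


def segment_electrodes_initial(
    ct: Volume,
    electrode_window: HUWindow = ELECTRODE_WINDOW,
    skull_window: HUWindow = SKULL_WINDOW,
    cross: StructuringElement = StructuringElement("cross", 3),
    ball: StructuringElement = StructuringElement("ball", 4),
) -> BinaryMask:
    """Initial electrode mask: HU threshold restricted to the brain region.

    May retain small bone fragments; refine with a brain mask from the
    registered MRI (:func:`refine_electrodes`) once registration has run.
    """
    electrodes = threshold_range(ct, electrode_window)
    skull = make_skull_mask(ct, skull_window, cross, ball)
    head = make_head_mask(ct)
    brain_region = make_brain_region_mask(head, make_no_skull_mask(skull))
    return BinaryMask.like(ct, electrodes.data & brain_region.data)


def make_sampling_mask(electrodes: BinaryMask) -> BinaryMask:
    """Registration sampling mask: all voxels that are NOT electrode."""
    return electrodes.complement()


def refine_electrodes(initial: BinaryMask, brain: BinaryMask) -> BinaryMask:
    """Keep only electrode voxels inside the brain mask."""
    if not initial.same_geometry(brain):
        raise GeometryError("electrode and brain masks are on different grids")
    return BinaryMask.like(initial, initial.data & brain.data)


def count_components(mask: BinaryMask, connectivity: int = 3) -> int:
    """Number of foreground components (default 26-connectivity)."""
    _, n = ndimage.label(mask.as_bool, structure=ndimage.generate_binary_structure(3, connectivity))
    return int(n)
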