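"""Brain extraction (skull stripping) from the registered MRI.

The fusion pipeline only needs *a* brain mask to discard bone fragments
from the electrode segmentation; high-fidelity skull stripping is treated
as an external dependency.  Three providers are offered:

``builtin``
    A deliberately simple surrogate: Otsu threshold, largest 26-connected
    component, morphological opening (ball radius 2), hole filling.
    Adequate on phantoms and roughly on T1 head MRI.
``command``
    Shell out to any user-supplied tool (e.g. ROBEX, BET) via a command
    template containing ``{in}`` and ``{out}`` placeholders.
``file``
    Load a precomputed mask (ground truth for phantoms).
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ContractError, ProviderError
from .segmentation import _fill_holes_3d
from .volume import BinaryMask, Volume, read_volume, write_volume

__all__ = ["extract_brain", "builtin_brain_mask"]


def builtin_brain_mask(mri: Volume) -> BinaryMask:
    data = np.asarray(mri.data, dtype=float)
    if data.min() == data.max():
        raise ContractError("Otsu threshold undefined for a constant image")
    fg = data > threshold_otsu(data)
    labels, n = ndimage.label(fg, structure=ndimage.generate_binary_structure(3, 3))
    if n == 0:
        raise ProviderError("builtin brain extraction found no foreground")
    largest = labels == (np.argmax(ndimage.sum_labels(fg, labels, range(1, n + 1))) + 1)
    r = 2
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball = (xx**2 + yy**2 + zz**2) <= r**2
    opened = ndimage.binary_opening(largest, structure=ball)
    if not opened.any():  # opening destroyed everything; fall back
        opened = largest
    # keep a single component after opening, then fill interior cavities
    labels, n = ndimage.label(opened, structure=ndimage.generate_binary_structure(3, 3))
    if n > 1:
        opened = labels == (np.argmax(ndimage.sum_labels(opened, labels, range(1, n + 1))) + 1)
    return BinaryMask.like(mri, _fill_holes_3d(opened).astype(np.uint8))


def extract_brain(
    mri: Volume,
    provider: str = "builtin",
    command: str | None = None,
    mask_path: str | Path | None = None,
) -> BinaryMask:
    """Compute (or load) a binary brain mask on the MRI grid."""
    if provider == "builtin":
        return builtin_brain_mask(mri)

    if provider == "command":
        if not command:
            raise ContractError("provider 'command' requires a command template")
        with tempfile.TemporaryDirectory() as tmp:
            in_path = Path(tmp) / "in.nii.gz"
            out_path = Path(tmp) / "mask.nii.gz"
            write_volume(mri, in_path)
            cmd = command.format(**{"in": str(in_path), "out": str(out_path)})
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise ProviderError(f"brain extraction command failed: {proc.stderr.strip()}")
            if not out_path.exists():
                raise ProviderError("brain extraction command produced no output file")
            mask = read_volume(out_path, mask=True)
            if not mask.same_geometry(mri):
                raise ProviderError("external brain mask geometry does not match the MRI")
            return mask

    if provider == "file":
        if mask_path is None:
            raise ContractError("provider 'file' requires mask_path")
        mask = read_volume(mask_path, mask=True)
        if not mask.same_geometry(mri):
            raise ProviderError("brain mask file geometry does not match the MRI")
        return mask

    raise ContractError(f"unknown brain provider {provider!r}")
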