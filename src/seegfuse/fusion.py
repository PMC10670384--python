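"""Merging segmented electrodes into the registered MRI.

The fused image is the registered MRI with electrode voxels overlaid at a
marker intensity (the MRI maximum by default, so electrodes render as the
brightest structure).  Overlay, not arithmetic addition: adding Hounsfield
units to MRI intensities would be unit-incoherent.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .volume import BinaryMask, Volume

__all__ = ["merge_electrodes"]


def merge_electrodes(
    registered_mri: Volume,
    electrodes: BinaryMask,
    marker: float | str = "max",
) -> Volume:
    """Overlay electrode voxels onto the MRI at the marker intensity.

    ``marker`` is either a fixed intensity or ``"max"`` (the MRI's maximum).
    Voxels outside the electrode mask are copied bit-exactly.
    """
    if not registered_mri.same_geometry(electrodes):
        raise GeometryError("MRI and electrode mask are on different grids")
    value = float(np.max(registered_mri.data)) if marker == "max" else float(marker)
    fused = registered_mri.data.copy()
    fused[electrodes.as_bool] = np.asarray(value).astype(fused.dtype)
    return registered_mri.with_data(fused)
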