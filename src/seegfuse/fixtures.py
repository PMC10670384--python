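"""Bundled reference fixtures for validating the error metrics.

Two families of small coordinate/error tables ship with the package:

* the eight RIRE-style field-of-view corner points (extent
  333.987 x 333.987 x 112 mm) and, per evaluation image, the corner
  positions mapped through a reference registration — the inputs of the
  fiducial-error protocol;
* a 64-value per-method registration-error table from the synthetic
  electrode evaluation (8 image pairs x 8 corners, masked and unmasked
  arms), whose medians and sample standard deviations are the method's
  headline numbers;
* clinical anatomical-structure localisations (Sylvian aqueduct, anterior
  commissure, lenses, pineal gland) in CT and in MRI registered with and
  without the sampling mask, with the corresponding printed distances.

Note on the clinical distance table: in the source material the two method
columns are transposed relative to the coordinate tables they derive from
(recomputing the distances from the coordinates reproduces the printed
values only with the "mask"/"no mask" labels swapped).  The loaders here
return the *numerically consistent* pairing: distances attributed to the
mask-registered MRI are those recomputable from the mask-registered
coordinates.
"""

from __future__ import annotations

import numpy as np

from .metrics import FiducialSet

__all__ = [
    "rire_corner_points",
    "rire_reference_points",
    "synthetic_validation_errors",
    "clinical_structures_ct",
    "clinical_structures_mri",
    "clinical_structure_distances",
    "CLINICAL_STRUCTURES",
]

_CORNER_EXTENT = (333.987, 333.987, 112.0)

_CORNERS = np.array([
    [0.0, 0.0, 0.0],
    [333.987, 0.0, 0.0],
    [0.0, 333.987, 0.0],
    [333.987, 333.987, 0.0],
    [0.0, 0.0, 112.0],
    [333.987, 0.0, 112.0],
    [0.0, 333.987, 112.0],
    [333.987, 333.987, 112.0],
])


def rire_corner_points() -> FiducialSet:
    """The eight original corner points (world mm)."""
    return FiducialSet.from_arrays([str(i + 1) for i in range(8)], _CORNERS.copy())


_REFERENCE_POINTS = {
    1: [[3.4167, -22.2013, -2.6957], [331.6863, -22.0400, -3.7915],
        [4.6098, 309.1427, 1.7573], [332.8794, 309.3039, 0.6615],
        [3.6098, -21.9385, 107.9271], [331.8794, -21.7772, 106.8313],
        [4.8029, 309.4055, 112.3801], [333.0724, 309.5667, 111.2843]],
    2: [[2.9734, -29.8271, -17.7596], [332.0465, -27.5075, -16.6379],
        [2.2699, 305.3511, -17.0817], [331.3430, 307.6706, -15.9600],
        [3.0988, -24.7405, 94.2014], [332.1718, -22.4210, 95.3231],
        [2.3953, 310.4376, 94.8793], [331.4683, 312.7571, 96.0010]],
    3: [[7.3801, -30.8327, -32.4198], [333.7592, -29.2687, -27.2289],
        [9.9346, 301.5044, -31.1614], [336.3137, 303.0685, -25.9705],
        [7.8149, -28.1302, 73.5445], [334.1940, -26.5661, 78.7354],
        [10.3693, 304.2070, 74.8029], [336.7485, 305.7711, 79.9938]],
    4: [[-4.4250, -22.1707, -6.5618], [327.7407, -21.7509, -8.7225],
        [-4.2159, 311.6391, -4.4026], [327.9498, 312.0588, -6.5633],
        [-4.0413, -22.2377, 106.3093], [328.1243, -21.8180, 104.1486],
        [-3.8322, 311.5720, 108.4685], [328.3335, 311.9917, 106.3078]],
    5: [[0.4343, -33.2795, -32.1174], [333.7756, -31.6846, -31.6177],
        [1.3211, 301.9878, -33.3221], [334.6624, 303.5827, -32.8224],
        [0.9893, -30.9427, 76.9555], [334.3306, -29.3477, 77.4553],
        [1.8761, 304.3246, 75.7508], [335.2174, 305.9196, 76.2505]],
    6: [[-14.1576, -32.7423, -23.8992], [308.7199, -34.2773, -26.0497],
        [-16.6352, 298.2377, -21.9366], [306.2424, 296.7028, -24.0871],
        [-13.7173, -30.1729, 85.4656], [309.1603, -31.7078, 83.3151],
        [-16.1948, 300.8072, 87.4282], [306.6827, 299.2722, 85.2777]],
    7: [[-7.6836, -35.2270, -19.1140], [330.7646, -33.7368, -18.2985],
        [-8.3642, 304.4994, -16.5283], [330.0840, 305.9896, -15.7128],
        [-7.7841, -37.0440, 92.8582], [330.6641, -35.5538, 93.6738],
        [-8.4647, 302.6823, 95.4439], [329.9835, 304.1725, 96.2594]],
    8: [[16.5968, -32.3464, -22.5351], [337.2910, -39.1214, -20.8741],
        [34.2465, 299.5795, -22.6286], [354.9407, 292.8044, -20.9676],
        [16.5872, -26.0946, 90.3929], [337.2813, -32.8696, 92.0538],
        [34.2369, 305.8313, 90.2994], [354.9310, 299.0562, 91.9603]],
}


def rire_reference_points(image: int) -> FiducialSet:
    """Corner points mapped through the reference registration, per image (1-8)."""
    return FiducialSet.from_arrays(
        [str(i + 1) for i in range(8)], np.asarray(_REFERENCE_POINTS[image], dtype=float)
    )


# 8 images x 8 corner points, masked and unmasked registration arms
_SYNTHETIC_ERRORS_MASK = [
    0.209, 0.367, 0.468, 0.159, 0.148, 0.489, 0.346, 0.228,
    1.260, 0.666, 1.446, 1.409, 1.204, 0.850, 1.386, 1.494,
    2.114, 1.553, 1.307, 1.279, 1.714, 0.987, 0.960, 0.972,
    1.247, 0.915, 1.507, 0.430, 0.843, 0.958, 1.344, 0.803,
    3.064, 3.059, 2.612, 1.601, 2.175, 1.832, 3.247, 2.223,
    0.737, 1.366, 1.595, 2.803, 1.594, 2.116, 1.661, 2.948,
    1.327, 0.954, 0.328, 0.614, 1.089, 0.615, 0.705, 0.899,
    3.161, 1.108, 3.041, 1.396, 3.258, 1.854, 3.014, 1.836,
]
_SYNTHETIC_ERRORS_NO_MASK = [
    0.179, 0.191, 0.131, 0.365, 0.258, 0.114, 0.174, 0.297,
    0.535, 0.617, 0.727, 0.586, 0.749, 0.870, 0.575, 0.496,
    3.469, 4.152, 6.576, 7.070, 5.029, 5.274, 8.033, 8.282,
    0.594, 1.015, 0.703, 0.415, 0.343, 0.827, 0.859, 0.553,
    2.998, 2.964, 2.584, 1.543, 2.189, 1.782, 3.209, 2.141,
    5.057, 17.157, 9.568, 21.541, 6.484, 17.945, 10.419, 22.187,
    0.909, 0.892, 0.436, 0.098, 0.598, 0.546, 0.611, 0.404,
    10.620, 5.676, 9.223, 7.952, 10.370, 6.935, 8.926, 8.886,
]


def synthetic_validation_errors() -> dict[str, np.ndarray]:
    """The 64 per-corner distances (mm) for each registration arm."""
    return {
        "mask": np.asarray(_SYNTHETIC_ERRORS_MASK),
        "no_mask": np.asarray(_SYNTHETIC_ERRORS_NO_MASK),
    }


CLINICAL_STRUCTURES = [
    "sylvian_aqueduct", "anterior_commissure", "right_lens", "left_lens", "pineal_gland",
]

_CLINICAL_CT = {
    1: [[1.619, 132.161, 128.294], [0.079, 149.323, 131.294], [30.48, 227.407, 121.907],
        [-39.392, 221.421, 120.383], [1.399, 132.381, 139.294]],
    2: [[1.719, 130.778, -390.919], [0.31, 145.902, -365.217], [30.951, 230.123, -365.558],
        [-38.422, 226.1, -367.741], [2.155, 125.729, -375.287]],
    3: [[-0.001, 133.384, -411.389], [-0.425, 170.072, -410.326], [29.609, 225.447, -457.272],
        [-36.389, 224.62, -453.821], [1.039, 141.247, -398.385]],
    4: [[6.398, 149.516, -571.414], [-0.19, 170.766, -565.312], [-0.743, 234.271, -598.263],
        [-54.969, 215.592, -584.7], [9.875, 147.018, -558.196]],
}

_CLINICAL_MRI_MASK = {
    1: [[-0.497, 135.501, 131.223], [-2.628, 159.994, 140.26], [31.231, 226.372, 126.957],
        [-38.222, 220.542, 124.31], [-0.381, 134.024, 139.112]],
    2: [[-0.941, 137.412, -374.917], [-2.127, 163.213, -365.627], [34.232, 237.695, -379.789],
        [-36.479, 233.46, -377.886], [-0.327, 131.274, -372.335]],
    3: [[-0.139, 146.147, -404.701], [-2.833, 169.993, -409.066], [28.638, 225.725, -456.317],
        [-37.283, 224.27, -452.711], [0.002, 143.884, -399.845]],
    4: [[3.085, 150.405, -571.851], [-0.279, 173.761, -569.139], [13.94, 230.782, -603.875],
        [-46.124, 228.076, -603.892], [5.151, 144.134, -566.054]],
}

_CLINICAL_MRI_NO_MASK = {
    1: [[-0.469, 136.396, 131.874], [-2.491, 160.081, 140.798], [31.606, 226.472, 127.22],
        [-38.372, 220.462, 124.4], [0.05, 131.032, 134.609]],
    2: [[-0.435, 134.905, -378.153], [-2.048, 158.782, -365.235], [33.893, 231.655, -370.27],
        [-36.656, 226.912, -371.566], [0.013, 129.051, -375.979]],
    3: [[1.229, 146.558, -405.057], [-0.905, 169.695, -409.541], [29.558, 226.22, -455.332],
        [-36.204, 224.27, -452.584], [1.401, 141.552, -399.967]],
    4: [[3.03, 151.037, -571.368], [-0.098, 173.599, -569.108], [14.847, 230.98, -603.507],
        [-45.157, 228.144, -605.603], [4.646, 144.436, -565.84]],
}

# Printed distance table, stored under the numerically consistent arm:
# "mask" rows reproduce |CT - mask-registered MRI| (the source prints these
# under its other column; see module docstring).
_CLINICAL_DISTANCES = {
    "mask": {
        1: [4.921, 14.198, 5.209, 4.191, 2.429],
        2: [17.526, 17.487, 16.451, 12.683, 6.754],
        3: [14.41, 2.719, 1.39, 1.468, 3.188],
        4: [3.458, 4.86, 16.101, 24.544, 9.612],
    },
    "no_mask": {
        1: [5.925, 14.583, 5.511, 4.254, 5.059],
        2: [13.588, 13.094, 5.762, 4.291, 4.013],
        3: [14.668, 0.994, 2.089, 1.299, 1.651],
        4: [3.696, 4.738, 16.774, 26.282, 9.615],
    },
}


def clinical_structures_ct(image: int) -> FiducialSet:
    """Anatomical-structure positions localised in the CT (image 1-4)."""
    return FiducialSet.from_arrays(CLINICAL_STRUCTURES, np.asarray(_CLINICAL_CT[image]))


def clinical_structures_mri(image: int, arm: str) -> FiducialSet:
    """Structure positions in the registered MRI; arm is 'mask' or 'no_mask'."""
    table = _CLINICAL_MRI_MASK if arm == "mask" else _CLINICAL_MRI_NO_MASK
    return FiducialSet.from_arrays(CLINICAL_STRUCTURES, np.asarray(table[image]))


def clinical_structure_distances(image: int, arm: str) -> np.ndarray:
    """Printed distances (mm), returned under the numerically consistent arm."""
    return np.asarray(_CLINICAL_DISTANCES[arm][image])
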