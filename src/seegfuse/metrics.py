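"""Registration-error and image-fusion quality metrics.

Fiducial (point) error is the Euclidean distance in world mm between a
reference point and the corresponding point produced by a registration:

    error = sqrt((PRx-Px)^2 + (PRy-Py)^2 + (PRz-Pz)^2)

Global fusion metrics compare two images on the same grid:

* mutual information MI(A,B) = H(A) + H(B) - H(A,B), joint-histogram
  estimate, base-2 logs (bits);
* SSIM as the mean over local windows of luminance^a * contrast^b *
  structure^c with the standard stabilisation constants;
* RMSE in a *literal* form — the square root of the SUM of squared voxel
  differences, no division — alongside the conventional normalised form
  (root of the mean).  The literal form is the default because it is the
  scale on which the reference results for this method are reported;
* PSNR derived from the literal RMSE as 10*log10((prod dims)^2 / RMSE),
  reported as +inf when RMSE is zero.

Error summaries report median, mean and sample standard deviation (n-1);
the headline statistic of the method's validation protocol is the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError, GeometryError
from .volume import Volume

__all__ = [
    "FiducialSet",
    "ErrorSummary",
    "EvaluationReport",
    "SsimParams",
    "euclidean_error",
    "fiducial_errors",
    "summarize_errors",
    "mutual_information_metric",
    "entropy_bits",
    "ssim_metric",
    "rmse_metric",
    "psnr_metric",
    "global_metrics",
]


@dataclass
class FiducialSet:
    """Ordered, labelled world-mm points (CSV columns: label,x_mm,y_mm,z_mm)."""

    labels: list[str]
    coords: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.labels = [str(label) for label in self.labels]
        if len(self.labels) != len(self.coords):
            raise ContractError("label count does not match point count")
        if len(set(self.labels)) != len(self.labels):
            raise ContractError("fiducial labels must be unique")
        if not np.isfinite(self.coords).all():
            raise ContractError("fiducial coordinates must be finite")

    @classmethod
    def from_arrays(cls, labels, coords) -> "FiducialSet":
        return cls(labels=list(labels), coords=np.asarray(coords, dtype=float))

    def __len__(self) -> int:
        return len(self.labels)

    def transformed(self, transform) -> "FiducialSet":
        return FiducialSet(labels=list(self.labels), coords=transform.apply(self.coords))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.coords, columns=["x_mm", "y_mm", "z_mm"])
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(labels=df["label"].astype(str).tolist(),
                   coords=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))


def euclidean_error(pr, p) -> float:
    """Euclidean distance in mm between a reference point and a test point."""
    return float(np.linalg.norm(np.asarray(pr, float) - np.asarray(p, float)))


def fiducial_errors(reference: FiducialSet, test: FiducialSet) -> np.ndarray:
    """Per-point distances; labels must match pairwise in order."""
    if reference.labels != test.labels:
        raise ContractError(
            f"fiducial labels differ: {reference.labels} vs {test.labels}"
        )
    return np.linalg.norm(reference.coords - test.coords, axis=1)


@dataclass
class ErrorSummary:
    median: float
    mean: float
    sd: float
    n: int
    min: float
    max: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("median", "mean", "sd", "n", "min", "max")}


def summarize_errors(errors) -> ErrorSummary:
    """Median / mean / sample sd (n-1 denominator) of a list of distances."""
    e = np.asarray(list(errors), dtype=float)
    if len(e) < 2:
        raise ContractError("need at least 2 values for a sample standard deviation")
    return ErrorSummary(
        median=float(np.median(e)),
        mean=float(np.mean(e)),
        sd=float(np.std(e, ddof=1)),
        n=int(len(e)),
        min=float(np.min(e)),
        max=float(np.max(e)),
    )


# --------------------------------------------------------------------------
# global image metrics


def _check_pair(a: Volume, b: Volume) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_geometry(b):
        raise GeometryError("metric inputs are on different grids")
    x = np.asarray(a.data, dtype=float).ravel()
    y = np.asarray(b.data, dtype=float).ravel()
    finite = np.isfinite(x) & np.isfinite(y)
    return x[finite], y[finite]


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count (or probability) array; 0*log0 = 0."""
    p = np.asarray(counts, dtype=float).ravel()
    total = p.sum()
    if total <= 0:
        raise ContractError("entropy of an empty distribution is undefined")
    p = p[p > 0] / total
    return float(-(p * np.log2(p)).sum())


def mutual_information_metric(a: Volume, b: Volume, bins: int = 64) -> float:
    """MI(A,B) = H(A) + H(B) - H(A,B) in bits, from a joint histogram."""
    x, y = _check_pair(a, b)
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    return entropy_bits(joint.sum(axis=1)) + entropy_bits(joint.sum(axis=0)) - entropy_bits(joint)


@dataclass(frozen=True)
class SsimParams:
    """Exponents and constants of the three-component SSIM."""

    alpha: float = 1.0  # luminance exponent
    beta: float = 1.0   # contrast exponent
    gamma: float = 1.0  # structure exponent
    k1: float = 0.01
    k2: float = 0.03
    win_size: int = 7

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ContractError("SSIM exponents must be non-negative")
        if self.win_size < 3 or self.win_size % 2 == 0:
            raise ContractError("SSIM window must be odd and >= 3")


def ssim_metric(a: Volume, b: Volume, p: SsimParams | None = None,
                data_range: float | None = None) -> float:
    """Mean local luminance^a * contrast^b * structure^c over uniform windows.

    With exponents (1,1,1) this reduces to the standard SSIM (uniform
    window, border cropped to full windows only).  Identical inputs give
    exactly 1.
    """
    p = p or SsimParams()
    if not a.same_geometry(b):
        raise GeometryError("SSIM inputs are on different grids")
    x = np.asarray(a.data, dtype=np.float64)
    y = np.asarray(b.data, dtype=np.float64)
    if data_range is None:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        data_range = float(hi - lo) or 1.0
    c1 = (p.k1 * data_range) ** 2
    c2 = (p.k2 * data_range) ** 2
    c3 = c2 / 2.0

    size = p.win_size
    mean = lambda im: ndimage.uniform_filter(im, size=size)
    mx, my = mean(x), mean(y)
    # unbiased local (co)variances, matching the usual SSIM estimator
    npix = size**3
    cov_norm = npix / (npix - 1)
    vx = cov_norm * (mean(x * x) - mx * mx)
    vy = cov_norm * (mean(y * y) - my * my)
    vxy = cov_norm * (mean(x * y) - mx * my)
    vx = np.maximum(vx, 0.0)
    vy = np.maximum(vy, 0.0)
    sx, sy = np.sqrt(vx), np.sqrt(vy)

    lum = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
    con = (2 * sx * sy + c2) / (vx + vy + c2)
    struct = (vxy + c3) / (sx * sy + c3)

    def powed(base: np.ndarray, expo: float) -> np.ndarray:
        if expo == 1.0:
            return base
        if float(expo).is_integer():
            return base ** int(expo)
        return np.sign(base) * np.abs(base) ** expo

    ssim_map = powed(lum, p.alpha) * powed(con, p.beta) * powed(struct, p.gamma)
    pad = (size - 1) // 2
    core = ssim_map[pad:-pad, pad:-pad, pad:-pad] if pad else ssim_map
    return float(core.mean())


def rmse_metric(a: Volume, b: Volume, normalized: bool = False) -> float:
    """Root of the summed squared differences (default) or of their mean."""
    x, y = _check_pair(a, b)
    ss = float(np.sum((x - y) ** 2))
    return math.sqrt(ss / len(x)) if normalized else math.sqrt(ss)


def psnr_metric(a: Volume, b: Volume) -> float:
    """10*log10((prod dims)^2 / literal RMSE); +inf when the images match."""
    rmse = rmse_metric(a, b, normalized=False)
    if rmse == 0.0:
        return math.inf
    n = float(np.prod(a.dims))
    return 10.0 * math.log10(n**2 / rmse)


def global_metrics(a: Volume, b: Volume, bins: int = 64) -> dict:
    """The four fusion-quality metrics as a plain dict."""
    return {
        "mi_bits": mutual_information_metric(a, b, bins=bins),
        "ssim": ssim_metric(a, b),
        "rmse": rmse_metric(a, b),
        "rmse_normalized": rmse_metric(a, b, normalized=True),
        "psnr": psnr_metric(a, b),
    }


@dataclass
class EvaluationReport:
    """Per-point errors plus summary statistics and optional global metrics."""

    labels: list[str]
    errors_mm: np.ndarray
    summary: ErrorSummary
    global_metrics: dict | None = None

    @classmethod
    def from_fiducials(cls, reference: FiducialSet, test: FiducialSet,
                       volumes: tuple[Volume, Volume] | None = None) -> "EvaluationReport":
        errs = fiducial_errors(reference, test)
        gm = global_metrics(*volumes) if volumes is not None else None
        return cls(labels=list(reference.labels), errors_mm=errs,
                   summary=summarize_errors(errs), global_metrics=gm)

    def to_dict(self) -> dict:
        out = {
            "per_point_mm": {lab: float(e) for lab, e in zip(self.labels, self.errors_mm)},
            "summary": self.summary.to_dict(),
        }
        if self.global_metrics is not None:
            out["global_metrics"] = {
                k: (None if math.isinf(v) else float(v)) for k, v in self.global_metrics.items()
            }
        return out
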