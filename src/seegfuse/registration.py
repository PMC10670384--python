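"""Rigid CT-MRI registration with an electrode-excluding sampling mask.

Mutual information is the standard similarity metric for CT/MRI because the
two modalities share structure but not intensities.  Implanted electrodes
break that assumption: they are bright in CT and absent from the MRI, so
metric samples drawn from electrode voxels pull the optimum away from the
anatomically correct pose.  The remedy implemented here is a *sampling
mask* on the fixed (CT) image — the complement of the segmented electrode
mask — restricting metric samples to non-electrode voxels.

The optimisation machinery (Mattes mutual information, regular-step
gradient descent, 3-level multi-resolution pyramid, seeded random
sampling) is SimpleITK's; this module owns the configuration, the mask
plumbing and the transform conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import ContractError, GeometryError, RegistrationError
from .transform import RigidTransform
from .volume import BinaryMask, Volume, resample_volume

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "initialize_transform",
    "register",
    "apply_transform",
]


@dataclass
class RegistrationConfig:
    """Knobs for the MI registration; defaults are conventional for head CT/MRI.

    mode:              'rigid' (6 DOF, default) or 'affine' (12 DOF).
    histogram_bins:    joint-histogram bins for Mattes MI.
    sampling_fraction: fraction of voxels sampled per iteration; samples are
                       drawn only where the sampling mask is 1 when given.
    shrink_factors / smoothing_sigmas: per-level pyramid schedule.
    learning_rate, min_step, max_iterations, relaxation: regular-step
                       gradient descent parameters (per level).
    seed:              RNG seed for metric sampling; fixed seed => same result.
    """

    mode: str = "rigid"
    histogram_bins: int = 50
    sampling_fraction: float = 0.2
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    learning_rate: float = 2.0
    min_step: float = 1e-4
    max_iterations: int = 300
    relaxation: float = 0.8
    convergence_tolerance: float = 1e-8
    init: str = "moments"  # 'moments' | 'geometry' | 'identity'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("rigid", "affine"):
            raise ContractError(f"mode must be 'rigid' or 'affine', got {self.mode!r}")
        if self.histogram_bins < 2:
            raise ContractError("histogram_bins must be >= 2")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ContractError("sampling_fraction must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ContractError("max_iterations must be >= 1")
        if len(self.shrink_factors) != len(self.smoothing_sigmas):
            raise ContractError("shrink_factors and smoothing_sigmas lengths differ")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    iterations_run: int
    converged: bool
    per_level_metric: list = field(default_factory=list)


def initialize_transform(fixed: Volume, moving: Volume, mode: str = "geometry") -> RigidTransform:
    """Identity rotation plus a translation aligning volume centers.

    ``geometry`` aligns the geometric centers of the two grids; ``moments``
    aligns intensity centroids.  The translation is expressed in the
    fixed-to-moving convention used throughout.
    """
    t0 = sitk.CenteredTransformInitializer(
        sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32),
        sitk.Cast(moving.to_sitk(), sitk.sitkFloat32),
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY
        if mode == "geometry"
        else sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    return RigidTransform.from_sitk(t0)


def register(
    fixed_ct: Volume,
    moving_mri: Volume,
    sampling_mask: BinaryMask | None = None,
    cfg: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Maximise (masked) mutual information between CT and MRI.

    When ``sampling_mask`` is given it must share the CT grid; metric samples
    are drawn only from voxels where it is 1.  Deterministic per cfg.seed.
    """
    cfg = cfg or RegistrationConfig()
    if sampling_mask is not None:
        if not sampling_mask.same_geometry(fixed_ct):
            raise GeometryError("sampling mask is not on the fixed CT grid")
        if not sampling_mask.data.any():
            raise ContractError("sampling mask is empty: no voxels to sample")

    fixed = sitk.Cast(fixed_ct.to_sitk(), sitk.sitkFloat32)
    moving = sitk.Cast(moving_mri.to_sitk(), sitk.sitkFloat32)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.histogram_bins)
    if cfg.sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(cfg.sampling_fraction, int(cfg.seed))
    if sampling_mask is not None:
        reg.SetMetricFixedMask(sampling_mask.to_sitk())

    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=cfg.learning_rate,
        minStep=cfg.min_step,
        numberOfIterations=cfg.max_iterations,
        relaxationFactor=cfg.relaxation,
        gradientMagnitudeTolerance=cfg.convergence_tolerance,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInterpolator(sitk.sitkLinear)

    if cfg.init == "identity":
        init = sitk.Euler3DTransform()
    else:
        init = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY
            if cfg.init == "geometry"
            else sitk.CenteredTransformInitializerFilter.MOMENTS,
        )
    if cfg.mode == "rigid":
        reg.SetInitialTransform(sitk.Euler3DTransform(init), inPlace=False)
    else:
        aff = sitk.AffineTransform(3)
        e = sitk.Euler3DTransform(init)
        aff.SetMatrix(e.GetMatrix())
        aff.SetTranslation(e.GetTranslation())
        aff.SetCenter(e.GetCenter())
        reg.SetInitialTransform(aff, inPlace=False)

    per_level: list[float] = []
    reg.AddCommand(sitk.sitkMultiResolutionIterationEvent,
                   lambda: per_level.append(float(reg.GetMetricValue()) if per_level else np.nan))

    try:
        final = reg.Execute(fixed, moving)
    except RuntimeError as exc:
        raise RegistrationError(f"registration failed: {exc}") from exc

    metric = float(reg.GetMetricValue())
    if not np.isfinite(metric):
        raise RegistrationError(
            f"non-finite metric after optimisation (stop: {reg.GetOptimizerStopConditionDescription()})"
        )
    iterations = int(reg.GetOptimizerIteration())
    stop = reg.GetOptimizerStopConditionDescription()
    return RegistrationResult(
        transform=RigidTransform.from_sitk(final),
        final_metric=metric,
        iterations_run=iterations,
        converged="Maximum number of iterations" not in stop,
        per_level_metric=per_level,
    )


def transform_point(t: RigidTransform, p) -> np.ndarray:
    """Affine action of ``t`` on a world-mm point (thin alias for t.apply)."""
    return t.apply(p)


def apply_transform(t: RigidTransform, moving: Volume, reference: Volume,
                    fill: float = 0.0) -> Volume:
    """Resample ``moving`` onto ``reference`` under ``t`` (linear interpolation)."""
    return resample_volume(moving, reference, t, interpolation="linear", fill=fill)
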