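"""2-point Dixon fat-fraction mapping and rigid VOI transfer.

The water/fat image pair yields a quantitative fat-fraction map

    I_ff = fat / (water + fat) * 1000,

stored as integer grey values 0..1000 (1 grey value = 0.1% fat).  Voxels
with zero total signal (air) are set to 0 and flagged in a validity mask,
keeping the map integer-valued.

To measure fat inside the T1-derived muscle VOI, the T1 volume is
registered onto the Dixon frame by rigid multimodal registration
(Mattes mutual information, multi-resolution, restricted to the hand),
and the resulting 6-DOF transform is applied to the VOI with
nearest-neighbour interpolation so mask values stay binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .core import (
    BinaryMask,
    ConfigError,
    DataError,
    GeometryError,
    RegistrationError,
    RigidTransform,
    VolumeImage,
    to_sitk,
)

__all__ = [
    "FatFractionImage",
    "RegistrationConfig",
    "compute_fat_fraction",
    "register_rigid",
    "transfer_voi",
]

FF_SCALE = 1000  # grey values per unit fat fraction (1 gv = 0.1% fat)


@dataclass(frozen=True, eq=False)
class FatFractionImage:
    """Integer fat-fraction map on the Dixon grid plus validity mask.

    ``image.data`` holds grey values in [0, 1000]; ``valid`` marks voxels
    where water + fat > 0 (elsewhere the map is 0 by convention).
    """

    image: VolumeImage
    valid: BinaryMask

    def __post_init__(self) -> None:
        d = self.image.data
        if d.min() < 0 or d.max() > FF_SCALE:
            raise DataError("fat-fraction grey values must lie in [0, 1000]")
        if not self.valid.same_grid(self.image):
            raise GeometryError("validity mask grid differs from fat-fraction grid")

    @property
    def data(self) -> np.ndarray:
        return self.image.data

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.image.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.image.origin

    def fraction(self) -> np.ndarray:
        """Fat fraction in [0, 1] as floats."""
        return self.image.data.astype(np.float64) / FF_SCALE


def compute_fat_fraction(water: VolumeImage, fat: VolumeImage) -> FatFractionImage:
    """Voxelwise ``round(fat / (water + fat) * 1000)``.

    Water and fat must share a grid and be non-negative.  Zero-denominator
    voxels get grey value 0 and are flagged invalid.
    """
    if not water.same_grid(fat):
        raise GeometryError("water and fat images are not on the same grid")
    w = np.asarray(water.data, dtype=np.float64)
    f = np.asarray(fat.data, dtype=np.float64)
    if w.min() < 0 or f.min() < 0:
        raise DataError("water/fat intensities must be >= 0")
    total = w + f
    valid = total > 0
    ff = np.zeros(w.shape, dtype=np.int16)
    ff[valid] = np.rint(f[valid] / total[valid] * FF_SCALE).astype(np.int16)
    return FatFractionImage(
        image=VolumeImage(ff, water.spacing, water.origin),
        valid=BinaryMask(valid, water.spacing, water.origin),
    )


@dataclass(frozen=True)
class RegistrationConfig:
    """Rigid multimodal registration parameters (Mattes MI)."""

    metric_bins: int = 32
    sampling_fraction: float = 0.25
    learning_rate: float = 1.0
    min_step: float = 1e-4
    max_iterations: int = 200
    levels: int = 2
    convergence_tolerance: float = 1e-6
    seed: int = 12345
    initialize: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.levels < 1:
            raise ConfigError("iteration cap and levels must be >= 1")
        if not (0 < self.sampling_fraction <= 1):
            raise ConfigError("sampling fraction must be in (0, 1]")


def _initial_transform(
    fixed: sitk.Image, moving: sitk.Image, initialize: bool
) -> sitk.Euler3DTransform:
    t = sitk.Euler3DTransform()
    if initialize:
        t = sitk.Euler3DTransform(
            sitk.CenteredTransformInitializer(
                fixed, moving, sitk.Euler3DTransform(),
                sitk.CenteredTransformInitializerFilter.MOMENTS,
            )
        )
    else:
        c = fixed.TransformContinuousIndexToPhysicalPoint(
            [(s - 1) / 2.0 for s in fixed.GetSize()]
        )
        t.SetCenter(c)
    return t


def _overlap_fraction(
    fixed: sitk.Image, moving_mask: sitk.Image, t: sitk.Transform
) -> float:
    """Fraction of fixed voxels that map into the moving foreground."""
    resampled = sitk.Resample(moving_mask, fixed, t, sitk.sitkNearestNeighbor, 0.0)
    arr = sitk.GetArrayFromImage(resampled)
    return float(arr.astype(bool).mean())


def register_rigid(
    t1: VolumeImage,
    t1_hand: BinaryMask,
    dixon_ref: VolumeImage,
    cfg: RegistrationConfig | None = None,
) -> tuple[RigidTransform, dict]:
    """Rigid multimodal registration of the T1 hand onto a Dixon-frame image.

    ``dixon_ref`` is any image on the Dixon grid (water image or
    fat-fraction map).  Returns the 6-DOF transform mapping Dixon-frame
    physical points into the T1 frame (the transform used to resample the
    T1-grid VOI onto the Dixon grid) together with diagnostics
    (final metric value, stop condition, initial overlap).
    """
    cfg = cfg or RegistrationConfig()
    if not t1_hand.same_grid(t1):
        raise GeometryError("hand mask must live on the T1 grid")
    if t1_hand.count() == 0:
        raise DataError("empty hand mask")

    fixed = to_sitk(dixon_ref, dtype=np.float32)
    moving = to_sitk(t1, dtype=np.float32)
    moving_mask = to_sitk(t1_hand, dtype=np.uint8)

    init = _initial_transform(fixed, moving, cfg.initialize)
    overlap = _overlap_fraction(fixed, moving_mask, init)
    if overlap <= 0:
        raise RegistrationError(
            "no overlap between the hand and the Dixon volume after initialization"
        )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.metric_bins)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(cfg.sampling_fraction, cfg.seed)
    reg.SetMetricMovingMask(moving_mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=cfg.learning_rate,
        minStep=cfg.min_step,
        numberOfIterations=cfg.max_iterations,
        gradientMagnitudeTolerance=cfg.convergence_tolerance,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (cfg.levels - 1 - i) for i in range(cfg.levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(init, inPlace=False)

    try:
        final = reg.Execute(fixed, moving)
    except RuntimeError as exc:
        raise RegistrationError(f"registration diverged: {exc}") from exc

    final = sitk.Euler3DTransform(
        final.GetNthTransform(0) if isinstance(final, sitk.CompositeTransform) else final
    )
    info = {
        "metric_value": float(reg.GetMetricValue()),
        "stop_condition": reg.GetOptimizerStopConditionDescription(),
        "iterations": int(reg.GetOptimizerIteration()),
        "initial_overlap": overlap,
    }
    return RigidTransform.from_sitk(final), info


def transfer_voi(
    muscle: BinaryMask, transform: RigidTransform, target: VolumeImage | FatFractionImage
) -> BinaryMask:
    """Resample the muscle VOI onto the target (Dixon) grid.

    Nearest-neighbour interpolation keeps the mask binary.  A transform
    that maps the whole VOI outside the target grid produces an empty mask
    with a warning, not an error.
    """
    tgt = target.image if isinstance(target, FatFractionImage) else target
    src = to_sitk(muscle, dtype=np.uint8)
    ref = to_sitk(tgt, dtype=np.float32)
    out = sitk.Resample(src, ref, transform.to_sitk(), sitk.sitkNearestNeighbor, 0.0)
    arr = sitk.GetArrayFromImage(out).astype(bool)
    if muscle.count() > 0 and not arr.any():
        warnings.warn("transferred VOI is empty on the target grid", stacklevel=2)
    return BinaryMask(arr, tgt.spacing, tgt.origin)
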