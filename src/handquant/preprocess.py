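"""T1 pre-processing: multiplicative bias-field removal and hand mask.

Bias correction is N4-style nonuniform intensity normalization (iterative
log-domain B-spline field estimation with histogram sharpening), delegated
to SimpleITK's ``N4BiasFieldCorrectionImageFilter``.  The estimated field is
rescaled so the corrected volume preserves the global mean intensity
exactly; correction therefore changes only the spatial modulation, not the
intensity scale.

The hand cross-sectional area is recovered slice by slice: automatic (or
fixed) thresholding, morphological closing, hole filling (so interior
hypointense structures — bone, tendons — are absorbed into the hand area)
and removal of small connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .core import (
    BinaryMask,
    ConfigError,
    DegenerateInputError,
    SegmentationError,
    VolumeImage,
    from_sitk,
    to_sitk,
)

__all__ = [
    "BiasCorrectionConfig",
    "HandMaskConfig",
    "correct_bias_field",
    "extract_hand_mask",
]


@dataclass(frozen=True)
class BiasCorrectionConfig:
    """N4 parameters.

    ``fitting_levels`` multi-resolution B-spline levels; ``max_iterations``
    per level; ``convergence_threshold`` on the coefficient-of-variation
    change between iterations; ``shrink_factor`` downsamples the volume for
    field estimation (the field is smooth, so estimation at reduced
    resolution loses nothing and is much faster).
    """

    fitting_levels: int = 3
    max_iterations: int = 50
    convergence_threshold: float = 1e-3
    shrink_factor: int = 2
    # The B-spline field is only identifiable where there is signal; beyond
    # this distance from the foreground the log field is decayed to 0
    # (field -> 1) instead of extrapolated.
    background_decay_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.fitting_levels < 1:
            raise ConfigError("iterations and fitting levels must be >= 1")
        if self.convergence_threshold <= 0:
            raise ConfigError("convergence threshold must be > 0")
        if self.shrink_factor < 1:
            raise ConfigError("shrink factor must be >= 1")
        if self.background_decay_mm <= 0:
            raise ConfigError("background decay length must be > 0")


@dataclass(frozen=True)
class HandMaskConfig:
    """Hand-mask extraction parameters.

    ``threshold`` is either the string ``"otsu-volume"`` (default; Otsu on
    the volume histogram, robust on slices without any hand),
    ``"otsu-slice"`` (Otsu per slice) or a fixed numeric value.
    ``closing_radius_vox`` is the in-plane structuring-disk radius;
    ``min_component_area_mm2`` drops per-slice components smaller than this.
    """

    threshold: str | float = "otsu-volume"
    closing_radius_vox: int = 2
    min_component_area_mm2: float = 30.0
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str) and self.threshold not in (
            "otsu-volume",
            "otsu-slice",
        ):
            raise ConfigError(f"unknown threshold strategy {self.threshold!r}")
        if self.closing_radius_vox < 0 or self.min_component_area_mm2 < 0:
            raise ConfigError("closing radius and minimum area must be >= 0")


def correct_bias_field(
    img: VolumeImage, cfg: BiasCorrectionConfig | None = None
) -> tuple[VolumeImage, VolumeImage]:
    """Estimate and remove a smooth multiplicative bias field.

    Returns ``(corrected, field)`` with ``corrected = img / field``.  The
    field is strictly positive and smooth; it is scaled so that the global
    mean of ``corrected`` equals the global mean of ``img``.
    """
    cfg = cfg or BiasCorrectionConfig()
    data = np.asarray(img.data, dtype=np.float64)
    if not np.any(data > 0):
        raise DegenerateInputError("bias correction needs a nonzero image")

    im = to_sitk(img, dtype=np.float32)
    # restrict the log-domain fit to foreground tissue
    fg = sitk.OtsuThreshold(im, 0, 1, 128)
    shrink = cfg.shrink_factor
    if shrink > 1:
        im_small = sitk.Shrink(im, [shrink] * 3)
        fg_small = sitk.Shrink(fg, [shrink] * 3)
    else:
        im_small, fg_small = im, fg
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([cfg.max_iterations] * cfg.fitting_levels)
    n4.SetConvergenceThreshold(cfg.convergence_threshold)
    n4.Execute(im_small, fg_small)
    log_field = n4.GetLogBiasFieldAsImage(im)
    log_arr = sitk.GetArrayFromImage(log_field).astype(np.float64)
    # The field is only identified on the foreground.  Replace the B-spline
    # extrapolation into air by a bounded smooth extension of the foreground
    # values (normalized convolution), decayed to 0 (field -> 1) with
    # physical distance from the tissue.
    fg_arr = sitk.GetArrayFromImage(fg).astype(bool)
    sampling = (img.spacing[2], img.spacing[1], img.spacing[0])
    sigma_vox = tuple(cfg.background_decay_mm / s for s in sampling)
    num = ndimage.gaussian_filter(np.where(fg_arr, log_arr, 0.0), sigma_vox)
    den = ndimage.gaussian_filter(fg_arr.astype(np.float64), sigma_vox)
    extended = np.where(den > 1e-8, num / np.maximum(den, 1e-8), 0.0)
    log_arr = np.where(fg_arr, log_arr, extended)
    dist = ndimage.distance_transform_edt(~fg_arr, sampling=sampling)
    log_arr *= np.exp(-((dist / cfg.background_decay_mm) ** 2))
    field_raw = np.exp(log_arr)

    # rescale so the corrected volume preserves the global mean exactly
    corrected_raw = data / field_raw
    s = corrected_raw.mean() / data.mean()
    field = field_raw * s
    corrected = corrected_raw / s
    return img.with_data(corrected.astype(np.float32)), img.with_data(
        field.astype(np.float32)
    )


def _slice_components(
    sl: np.ndarray, radius: int, min_area_px: float, fill: bool
) -> np.ndarray:
    if radius > 0:
        sl = ndimage.binary_closing(sl, structure=disk(radius))
    if fill:
        sl = ndimage.binary_fill_holes(sl)
    if min_area_px > 0:
        lab, n = ndimage.label(sl)
        if n:
            counts = np.bincount(lab.ravel())
            keep = np.flatnonzero(counts >= min_area_px)
            keep = keep[keep > 0]
            sl = np.isin(lab, keep)
    return sl


def extract_hand_mask(img: VolumeImage, cfg: HandMaskConfig | None = None) -> BinaryMask:
    """Per-slice hand cross-sectional-area mask.

    Threshold -> morphological closing -> hole filling -> minimum-area
    filter, slice by slice; the union over slices is the hand mask.  Slices
    with no hand simply yield empty contours; an entirely empty result
    raises :class:`SegmentationError`.
    """
    cfg = cfg or HandMaskConfig()
    data = np.asarray(img.data, dtype=np.float64)
    dx, dy, _ = img.spacing
    min_area_px = cfg.min_component_area_mm2 / (dx * dy)

    if isinstance(cfg.threshold, (int, float)):
        thr_volume: float | None = float(cfg.threshold)
    elif cfg.threshold == "otsu-volume":
        if np.ptp(data) == 0:
            raise SegmentationError("constant image: no threshold separates hand from air")
        thr_volume = float(threshold_otsu(data))
    else:  # otsu-slice
        thr_volume = None

    out = np.zeros(data.shape, dtype=bool)
    for k in range(data.shape[0]):
        sl = data[k]
        if thr_volume is None:
            if np.ptp(sl) == 0:
                continue
            thr = float(threshold_otsu(sl))
        else:
            thr = thr_volume
        binary = sl > thr
        if not binary.any():
            continue
        out[k] = _slice_components(binary, cfg.closing_radius_vox, min_area_px, cfg.fill_holes)

    if not out.any():
        raise SegmentationError("hand mask empty on every slice")
    return BinaryMask.like(img, out)
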