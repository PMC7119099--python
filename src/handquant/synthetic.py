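"""Synthetic hand phantoms and cohorts with known ground truth.

The phantom is deliberately schematic — a palm slab with finger cylinders,
containing muscle, bone, tendon and vessel compartments — because the
segmentation pipeline only needs intensity contrast, connectivity and
hypo-/hyperintense distractor structures, not anatomy.  The default grid
(96 x 96 in-plane, 24 slices at 1.0 x 1.0 x 3.0 mm) is a desk-scale
downscaling of the clinical acquisition geometry (320 x 320 at
0.5 x 0.5 mm, 64 T1 / 30 Dixon slices, 3.0 mm thickness); full-size
generation is a matter of changing ``PhantomSpec.shape``/``spacing``.

The T1 volume is ``tissue mean x multiplicative bias field + Gaussian
noise``; the bias field is the exponential of a smooth random field, the
form N4-style correction assumes.  The Dixon pair lives on its own
coarser grid, displaced from the T1 grid by a stored rigid transform, and
satisfies ``fat / (water + fat) = true fat fraction`` per compartment
exactly before noise.

The cohort generator draws per-subject demographics and outcome variables
from a linear-in-age model with sex- and disease-specific intercepts and
slopes, mirroring the observed cohort structure of the three patient
groups (psoriasis Pso — the control group — psoriatic arthritis PsA and
rheumatoid arthritis RA, with group sizes 63/38/61/76/41/51 by
diagnosis x sex).  The true generating coefficients are returned alongside
so statistical recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage
from scipy.stats import truncnorm

from .core import (
    AnalysisBounds,
    BinaryMask,
    DataError,
    RigidTransform,
    VolumeImage,
    from_sitk,
    to_sitk,
    voxel_volume,
)

__all__ = [
    "LABELS",
    "PhantomSpec",
    "PhantomTruth",
    "generate_hand_phantom",
    "CohortSpec",
    "CohortGroup",
    "generate_cohort",
    "perturb_for_reanalysis",
]

# Compartment labels used in PhantomTruth.labels
LABELS: Mapping[str, int] = {
    "background": 0,
    "other": 1,       # unspecified soft tissue / suppressed subcutaneous fat
    "muscle": 2,
    "bone": 3,
    "tendon": 4,      # hypointense distractor
    "vessel": 5,      # hyperintense distractor
}

# T1 is fat-suppressed: fat-rich "other" tissue is mid-grey, muscle bright-ish,
# tendons/bone dark, vessels bright.  Arbitrary units; only contrast matters.
_DEFAULT_T1_MEANS = {
    "background": 5.0,
    "other": 55.0,
    "muscle": 100.0,
    "bone": 30.0,
    "tendon": 25.0,
    "vessel": 220.0,
}

# Proton-density-like total Dixon signal (water + fat) per compartment.
_DEFAULT_DIXON_TOTAL = {
    "background": 2.0,
    "other": 300.0,
    "muscle": 300.0,
    "bone": 200.0,
    "tendon": 250.0,
    "vessel": 300.0,
}

_DEFAULT_FAT_FRACTIONS = {
    "background": 0.0,
    "other": 0.6,     # subcutaneous / connective tissue
    "muscle": 0.10,   # intramuscular fat, a few percent to ~10% is typical
    "bone": 0.5,      # marrow
    "tendon": 0.05,
    "vessel": 0.05,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic hand scan.

    ``shape`` is ``(slices, rows, cols)``; ``spacing`` is ``(dx, dy, dz)``
    in mm.  ``bias_amplitude`` is the peak of |log field|, so the field
    ranges over roughly ``[exp(-a), exp(a)]``; ``bias_scale_mm`` is the
    correlation length of the smooth field.  ``dixon_transform`` maps
    Dixon-grid physical points into the T1 frame (the transform a rigid
    registration of the T1 scan onto the Dixon scan should recover).
    """

    shape: tuple[int, int, int] = (24, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    t1_means: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_T1_MEANS))
    dixon_total: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DIXON_TOTAL))
    fat_fractions: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_FAT_FRACTIONS))
    noise_sd: float = 4.0
    dixon_noise_sd: float = 3.0
    bias_amplitude: float = 0.2
    bias_scale_mm: float = 40.0
    dixon_n_slices: int = 12
    dixon_transform: RigidTransform = field(
        default_factory=lambda: RigidTransform(
            rotation_deg=(0.0, 0.0, 5.0), translation_mm=(2.5, 3.0, 1.0)
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise DataError(f"phantom grid {self.shape} too small for the hand geometry")
        if any(v < 0 for v in self.t1_means.values()):
            raise DataError("tissue intensities must be >= 0")
        if any(not (0.0 <= f <= 1.0) for f in self.fat_fractions.values()):
            raise DataError("fat fractions must lie in [0, 1]")
        if self.noise_sd < 0 or self.dixon_noise_sd < 0 or self.bias_amplitude < 0:
            raise DataError("noise and bias amplitudes must be >= 0")
        if not (0 < self.dixon_n_slices <= self.shape[0]):
            raise DataError("dixon_n_slices must be in (0, n_slices]")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying one phantom."""

    labels: VolumeImage            # int labels on the T1 grid
    dixon_labels: VolumeImage      # int labels on the Dixon grid
    bias_field: VolumeImage        # multiplicative field applied to T1
    transform: RigidTransform      # Dixon -> T1 frame mapping
    bounds: AnalysisBounds         # slices containing hand tissue
    v_h: float                     # mm^3, hand volume within bounds
    v_m: float                     # mm^3
    v_m_rel: float
    v_f: float                     # mm^3, fat within the muscle compartment
    v_f_rel: float

    def hand_mask(self) -> BinaryMask:
        return BinaryMask.like(self.labels, self.labels.data > 0)

    def muscle_mask(self) -> BinaryMask:
        return BinaryMask.like(self.labels, self.labels.data == LABELS["muscle"])

    def dixon_muscle_mask(self) -> BinaryMask:
        return BinaryMask.like(self.dixon_labels, self.dixon_labels.data == LABELS["muscle"])

    def dixon_v_m(self) -> float:
        """Muscle volume (mm^3) within the Dixon grid coverage."""
        return self.dixon_muscle_mask().count() * voxel_volume(self.dixon_labels)

    def dixon_v_f(self, muscle_fat_fraction: float) -> float:
        """Fat volume (mm^3) within the Dixon-grid muscle compartment."""
        return self.dixon_v_m() * muscle_fat_fraction


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

def _paint_labels(shape: tuple[int, int, int]) -> np.ndarray:
    """Schematic hand: palm slab + 4 finger cylinders, with internal
    muscle/bone/tendon/vessel compartments.  Coordinates scale with the grid."""
    ns, nr, nc = shape
    lab = np.zeros(shape, dtype=np.int16)
    r = np.arange(nr)[:, None].astype(float) / (nr - 1)   # 0..1 row coord
    c = np.arange(nc)[None, :].astype(float) / (nc - 1)   # 0..1 col coord

    def ellipse(rc, cc, rr, cr):
        return ((r - rc) / rr) ** 2 + ((c - cc) / cr) ** 2 <= 1.0

    # hand cross-section (constant over the hand slices)
    palm = ellipse(0.42, 0.50, 0.26, 0.33)
    fingers = np.zeros_like(palm)
    for ck in (0.26, 0.42, 0.58, 0.74):
        fingers |= (r >= 0.60) & (r <= 0.92) & (np.abs(c - ck) <= 0.045)
    hand2d = palm | fingers

    muscle2d = (
        ellipse(0.36, 0.30, 0.115, 0.10)     # thenar-like blob
        | ellipse(0.36, 0.70, 0.115, 0.10)   # hypothenar-like blob
        | ellipse(0.52, 0.50, 0.09, 0.24)    # interossei-like strip
    ) & palm
    bone2d = np.zeros_like(palm)
    for ck in (0.32, 0.44, 0.56, 0.68):
        bone2d |= ellipse(0.42, ck, 0.045, 0.032)
    bone2d &= palm
    tendon2d = np.zeros_like(palm)
    for ck in (0.38, 0.50, 0.62):
        tendon2d |= ellipse(0.58, ck, 0.028, 0.018)
    tendon2d &= palm
    vessel2d = (ellipse(0.30, 0.50, 0.022, 0.016) | ellipse(0.46, 0.24, 0.022, 0.016)) & palm

    # paint in priority order (later wins)
    sect = np.zeros((nr, nc), dtype=np.int16)
    sect[hand2d] = LABELS["other"]
    sect[muscle2d] = LABELS["muscle"]
    sect[tendon2d] = LABELS["tendon"]
    sect[vessel2d] = LABELS["vessel"]
    sect[bone2d] = LABELS["bone"]

    z0, z1 = max(1, ns // 8), ns - max(1, ns // 8) - 1   # leave empty end slices
    lab[z0 : z1 + 1] = sect[None, :, :]
    return lab


def _smooth_bias_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    amplitude: float,
    scale_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """exp(smooth field); peak |log field| equals ``amplitude``."""
    if amplitude == 0:
        return np.ones(shape)
    # Gaussian-filtered white noise; sigma in voxels per axis from the
    # physical correlation length.  Axis order (slice,row,col) = (dz,dy,dx).
    sig = (scale_mm / spacing[2], scale_mm / spacing[1], scale_mm / spacing[0])
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sig, mode="nearest")
    g -= g.mean()
    peak = np.abs(g).max()
    if peak == 0:
        return np.ones(shape)
    return np.exp(amplitude * g / peak)


def _dixon_reference(spec: PhantomSpec) -> sitk.Image:
    """Empty Dixon-grid image: same in-plane grid, central subset of slices."""
    ns = spec.shape[0]
    nz = spec.dixon_n_slices
    z_off = (ns - nz) // 2
    ref = sitk.Image(spec.shape[2], spec.shape[1], nz, sitk.sitkFloat32)
    ref.SetSpacing(spec.spacing)
    ref.SetOrigin(
        (spec.origin[0], spec.origin[1], spec.origin[2] + z_off * spec.spacing[2])
    )
    return ref


def generate_hand_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeImage, VolumeImage, VolumeImage, PhantomTruth]:
    """Generate one T1 + Dixon water/fat phantom with ground truth.

    Returns ``(t1, dixon_water, dixon_fat, truth)``.  Bit-identical output
    for identical specs (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    labels = _paint_labels(spec.shape)
    names = list(LABELS)

    t1_mean_lut = np.array([spec.t1_means[n] for n in names])
    field_arr = _smooth_bias_field(
        spec.shape, spec.spacing, spec.bias_amplitude, spec.bias_scale_mm, rng
    )
    t1_data = t1_mean_lut[labels] * field_arr
    if spec.noise_sd > 0:
        t1_data = t1_data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    t1_data = np.clip(t1_data, 0.5, None)
    t1 = VolumeImage(t1_data.astype(np.float32), spec.spacing, spec.origin)

    # center the rigid transform on the volume so default rotations stay local
    center = tuple(
        spec.origin[i] + 0.5 * spec.spacing[i] * (spec.shape[2 - i] - 1) for i in range(3)
    )
    transform = replace(spec.dixon_transform, center_mm=center)

    # Dixon-grid labels: nearest-neighbour resampling through the transform
    lab_img = to_sitk(VolumeImage(labels.astype(np.float32), spec.spacing, spec.origin))
    ref = _dixon_reference(spec)
    lab_dixon = sitk.Resample(
        lab_img, ref, transform.to_sitk(), sitk.sitkNearestNeighbor, 0.0
    )
    dixon_labels = np.rint(sitk.GetArrayFromImage(lab_dixon)).astype(np.int16)

    total_lut = np.array([spec.dixon_total[n] for n in names])
    ff_lut = np.array([spec.fat_fractions[n] for n in names])
    total = total_lut[dixon_labels]
    ff = ff_lut[dixon_labels]
    water_data = total * (1.0 - ff)
    fat_data = total * ff
    if spec.dixon_noise_sd > 0:
        water_data = np.clip(
            water_data + rng.normal(0.0, spec.dixon_noise_sd, water_data.shape), 0.0, None
        )
        fat_data = np.clip(
            fat_data + rng.normal(0.0, spec.dixon_noise_sd, fat_data.shape), 0.0, None
        )
    d_spacing = tuple(ref.GetSpacing())
    d_origin = tuple(ref.GetOrigin())
    water = VolumeImage(water_data.astype(np.float32), d_spacing, d_origin)
    fat = VolumeImage(fat_data.astype(np.float32), d_spacing, d_origin)

    # truth bookkeeping: volumes are exact voxel counts x voxel volume
    vv = voxel_volume(t1)
    hand_slices = np.flatnonzero((labels > 0).any(axis=(1, 2)))
    bounds = AnalysisBounds(int(hand_slices[0]), int(hand_slices[-1]))
    n_hand = int((labels > 0).sum())
    n_muscle = int((labels == LABELS["muscle"]).sum())
    v_h = n_hand * vv
    v_m = n_muscle * vv
    v_f = n_muscle * vv * spec.fat_fractions["muscle"]
    truth = PhantomTruth(
        labels=VolumeImage(labels, spec.spacing, spec.origin),
        dixon_labels=VolumeImage(dixon_labels, d_spacing, d_origin),
        bias_field=VolumeImage(field_arr, spec.spacing, spec.origin),
        transform=transform,
        bounds=bounds,
        v_h=v_h,
        v_m=v_m,
        v_m_rel=v_m / v_h,
        v_f=v_f,
        v_f_rel=(v_f / v_m) if v_m else 0.0,
    )
    return t1, water, fat, truth


# ---------------------------------------------------------------------------
# Reanalysis perturbation
# ---------------------------------------------------------------------------

def perturb_for_reanalysis(
    t1: VolumeImage, magnitude: float, seed: int
) -> VolumeImage:
    """Add small Gaussian intensity noise emulating operator-to-operator
    variability in repeated analyses of the same scan.

    ``magnitude`` is the noise SD in image intensity units; 0 returns an
    identical copy.  For a fixed seed the perturbation scales linearly with
    ``magnitude``, so the voxelwise RMS difference is monotone in it.
    """
    if magnitude < 0:
        raise DataError("perturbation magnitude must be >= 0")
    if magnitude == 0:
        return t1.with_data(t1.data.copy())
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(t1.data.shape)
    return t1.with_data((t1.data + magnitude * noise).astype(np.float32))


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGroup:
    """Sample size and age distribution of one diagnosis x sex cell."""

    n: int
    age_mean: float
    age_sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError("each group needs n >= 2")
        if self.age_sd <= 0:
            raise DataError("age SD must be > 0")


# Observed cohort structure: (diagnosis, sex) -> n, age mean +- SD.
_DEFAULT_GROUPS = {
    ("Pso", "male"): CohortGroup(63, 48.0, 12.0),
    ("Pso", "female"): CohortGroup(38, 54.0, 15.0),
    ("PsA", "male"): CohortGroup(61, 56.0, 14.0),
    ("PsA", "female"): CohortGroup(76, 56.0, 11.0),
    ("RA", "male"): CohortGroup(41, 62.0, 12.0),
    ("RA", "female"): CohortGroup(51, 60.0, 14.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a synthetic cross-sectional cohort.

    Outcomes follow ``y = intercept[sex] + offset[diagnosis] +
    slope[sex] * (age - 40) + bmi_slope * (bmi - bmi_mean) + N(0, sd)``,
    with Pso as the zero-offset control group.  Ages are truncated normal
    on [20, 80]; BMI is present for ``bmi_fraction`` of subjects (the
    subset with BMI available in the clinical cohort was 206/330).
    """

    groups: Mapping[tuple[str, str], CohortGroup] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )
    age_range: tuple[float, float] = (20.0, 80.0)
    # relative muscle volume (dimensionless)
    vmrel_intercept: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.220, "female": 0.193}
    )
    vmrel_age_slope: Mapping[str, float] = field(
        default_factory=lambda: {"male": -7.0e-4, "female": -5.0e-4}
    )
    vmrel_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"Pso": 0.0, "PsA": -0.006, "RA": -0.035}
    )
    vmrel_bmi_slope: float = 0.0
    vmrel_sd: float = 0.025
    # hand volume (cm^3)
    vh_intercept: Mapping[str, float] = field(
        default_factory=lambda: {"male": 400.0, "female": 292.0}
    )
    vh_age_slope: Mapping[str, float] = field(
        default_factory=lambda: {"male": -0.3, "female": 0.5}
    )
    vh_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"Pso": 0.0, "PsA": 0.0, "RA": -8.0}
    )
    vh_bmi_slope: float = 0.0
    vh_sd: float = 40.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    bmi_fraction: float = 206.0 / 330.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmrel_sd < 0 or self.vh_sd < 0 or self.bmi_sd <= 0:
            raise DataError("SDs must be positive (residual SDs >= 0)")
        if not (0.0 <= self.bmi_fraction <= 1.0):
            raise DataError("bmi_fraction must be in [0, 1]")

    def true_coefficients(self) -> dict:
        """The generating coefficients, for recovery tests."""
        return {
            "vmrel": {
                "intercept": dict(self.vmrel_intercept),
                "age_slope": dict(self.vmrel_age_slope),
                "offsets": dict(self.vmrel_offsets),
                "bmi_slope": self.vmrel_bmi_slope,
                "sd": self.vmrel_sd,
            },
            "vh": {
                "intercept": dict(self.vh_intercept),
                "age_slope": dict(self.vh_age_slope),
                "offsets": dict(self.vh_offsets),
                "bmi_slope": self.vh_bmi_slope,
                "sd": self.vh_sd,
            },
            "age_anchor": 40.0,
        }


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic cohort table.

    Returns ``(table, true_coefficients)``.  Columns: ``id, sex, diagnosis,
    age, bmi, vh, vm, vmrel`` — BMI is NaN where unavailable; ``vm`` is
    derived as ``vmrel * vh`` so the record-level identity holds exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    i = 0
    for (diag, sex), grp in spec.groups.items():
        ages = _truncated_normal(
            rng, grp.age_mean, grp.age_sd, spec.age_range[0], spec.age_range[1], grp.n
        )
        bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, grp.n)
        has_bmi = rng.random(grp.n) < spec.bmi_fraction
        bmi = np.where(has_bmi, bmi, np.nan)
        bmi_c = np.where(has_bmi, bmi - spec.bmi_mean, 0.0)
        vmrel = (
            spec.vmrel_intercept[sex]
            + spec.vmrel_offsets[diag]
            + spec.vmrel_age_slope[sex] * (ages - 40.0)
            + spec.vmrel_bmi_slope * bmi_c
            + rng.normal(0.0, spec.vmrel_sd, grp.n)
        )
        vh = (
            spec.vh_intercept[sex]
            + spec.vh_offsets[diag]
            + spec.vh_age_slope[sex] * (ages - 40.0)
            + spec.vh_bmi_slope * bmi_c
            + rng.normal(0.0, spec.vh_sd, grp.n)
        )
        vmrel = np.clip(vmrel, 1e-6, 1.0)
        vh = np.clip(vh, 1.0, None)
        for k in range(grp.n):
            rows.append(
                {
                    "id": f"S{i:04d}",
                    "sex": sex,
                    "diagnosis": diag,
                    "age": float(ages[k]),
                    "bmi": float(bmi[k]),
                    "vh": float(vh[k]),
                    "vm": float(vmrel[k] * vh[k]),
                    "vmrel": float(vmrel[k]),
                }
            )
            i += 1
    return pd.DataFrame(rows), spec.true_coefficients()
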