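"""Output parameters and reanalysis precision.

Volumetrics: within the analysis bounds (proximal/distal MCP-III slices),
hand volume V_H and muscle volume V_M are the accumulated volumes of all
voxels in the respective segmentations; the relative muscle volume is
V_M^rel = V_M / V_H.  On the Dixon grid the absolute fat volume is
V_F = sum over muscle voxels of voxel_volume * I_ff / 1000 and the
relative fat content V_F^rel = V_F / V_M (with V_M recomputed on the
Dixon grid so numerator and denominator share a grid).

Reanalysis precision follows densitometry convention: per dataset the
standard deviation (n-1 denominator) and the coefficient of variation
SD / mean over repeated analyses, then the root-mean-square average of
each across datasets (RMS-SD in the unit of the variable, RMS-CV in %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AnalysisBounds,
    BinaryMask,
    DataError,
    GeometryError,
    InsufficientDataError,
    voxel_volume,
)
from .dixon import FF_SCALE, FatFractionImage
from .muscle import restrict_to_bounds

__all__ = [
    "HandMetrics",
    "PrecisionReport",
    "compute_hand_metrics",
    "compute_fat_metrics",
    "precision_errors",
]


@dataclass(frozen=True)
class HandMetrics:
    """Per-scan output parameters (volumes in mm^3)."""

    v_h: float
    v_m: float
    v_m_rel: float
    v_f: float | None = None
    v_f_rel: float | None = None
    bounds: AnalysisBounds | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        if self.v_m > self.v_h + 1e-9:
            raise DataError("V_M cannot exceed V_H")
        if self.v_f is not None and self.v_f_rel is None:
            raise DataError("V_F_rel must accompany V_F")

    def to_dict(self) -> dict:
        d = {
            "scan_id": self.scan_id,
            "v_h_mm3": self.v_h,
            "v_m_mm3": self.v_m,
            "v_m_rel": self.v_m_rel,
        }
        if self.bounds is not None:
            d["bounds"] = [self.bounds.proximal_slice, self.bounds.distal_slice]
        if self.v_f is not None:
            d["v_f_mm3"] = self.v_f
            d["v_f_rel"] = self.v_f_rel
        return d


def compute_hand_metrics(
    hand: BinaryMask,
    muscle: BinaryMask,
    bounds: AnalysisBounds,
    scan_id: str = "",
) -> HandMetrics:
    """V_H, V_M and V_M^rel within the inclusive slice bounds.

    ``muscle`` must be a subset of ``hand`` on the same grid; volumes are
    exactly voxel counts times the voxel volume.
    """
    if not muscle.same_grid(hand):
        raise GeometryError("hand and muscle masks are not on the same grid")
    if not muscle.is_subset_of(hand):
        raise DataError("muscle mask is not contained in the hand mask")
    bounds.validate_for(hand.data.shape[0])
    vv = voxel_volume(hand)
    n_h = restrict_to_bounds(hand, bounds).count()
    n_m = restrict_to_bounds(muscle, bounds).count()
    if n_h == 0:
        raise DataError("no hand voxels within the analysis bounds: V_M_rel undefined")
    v_h = n_h * vv
    v_m = n_m * vv
    return HandMetrics(v_h=v_h, v_m=v_m, v_m_rel=v_m / v_h, bounds=bounds, scan_id=scan_id)


def compute_fat_metrics(
    ff: FatFractionImage, muscle_on_ff: BinaryMask
) -> tuple[float, float]:
    """(V_F in mm^3, V_F^rel) within the Dixon-grid muscle VOI.

    V_F accumulates voxel_volume * I_ff/1000 over muscle voxels; V_F^rel
    divides by the Dixon-grid muscle volume.
    """
    if not muscle_on_ff.same_grid(ff.image):
        raise GeometryError("muscle VOI and fat-fraction map are not on the same grid")
    n = muscle_on_ff.count()
    if n == 0:
        raise DataError("empty muscle VOI on the Dixon grid: V_F_rel undefined")
    vv = voxel_volume(ff.image)
    sel = muscle_on_ff.as_bool()
    v_f = float(vv * (ff.data[sel].astype(np.float64) / FF_SCALE).sum())
    v_m = n * vv
    return v_f, v_f / v_m


@dataclass(frozen=True)
class PrecisionReport:
    """RMS-SD and RMS-CV per output parameter over repeated analyses."""

    mode: str                                  # "inter-operator" | "intra-operator"
    n_datasets: int
    n_repeats: int                             # minimum repeats per dataset
    rms_sd: dict = field(default_factory=dict)       # parameter -> RMS-SD (units)
    rms_cv_pct: dict = field(default_factory=dict)   # parameter -> RMS-CV (%)
    zero_mean_flags: dict = field(default_factory=dict)  # parameter -> [dataset ids]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_datasets": self.n_datasets,
            "n_repeats": self.n_repeats,
            "rms_sd": dict(self.rms_sd),
            "rms_cv_pct": dict(self.rms_cv_pct),
            "zero_mean_flags": {k: list(v) for k, v in self.zero_mean_flags.items()},
        }


def precision_errors(
    measurements: pd.DataFrame,
    mode: str = "inter-operator",
    parameters: tuple[str, ...] | None = None,
) -> PrecisionReport:
    """Reanalysis precision from a long table of repeated measurements.

    ``measurements`` needs columns ``dataset`` and ``repeat`` plus one
    column per parameter.  Per dataset the SD (ddof=1) and CV = SD/mean
    are computed; the report carries the RMS over datasets of each.
    Datasets with zero mean are excluded from RMS-CV and flagged.
    """
    if mode not in ("inter-operator", "intra-operator"):
        raise DataError(f"unknown precision mode {mode!r}")
    required = {"dataset", "repeat"}
    if not required.issubset(measurements.columns):
        raise DataError(f"measurements table needs columns {sorted(required)}")
    if parameters is None:
        parameters = tuple(c for c in measurements.columns if c not in required)
    if not parameters:
        raise DataError("no parameter columns in measurements table")
    counts = measurements.groupby("dataset")["repeat"].count()
    if len(counts) < 1:
        raise InsufficientDataError("need at least one dataset")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise InsufficientDataError(f"datasets with fewer than 2 repeats: {bad}")

    rms_sd: dict = {}
    rms_cv: dict = {}
    flags: dict = {}
    grouped = measurements.groupby("dataset")
    for p in parameters:
        sds, cvs, flagged = [], [], []
        for ds, grp in grouped:
            vals = np.asarray(grp[p], dtype=np.float64)
            sd = float(np.std(vals, ddof=1))
            mean = float(np.mean(vals))
            sds.append(sd)
            if mean == 0:
                flagged.append(ds)
            else:
                cvs.append(sd / mean)
        rms_sd[p] = float(np.sqrt(np.mean(np.square(sds))))
        rms_cv[p] = float(100.0 * np.sqrt(np.mean(np.square(cvs)))) if cvs else float("nan")
        if flagged:
            flags[p] = flagged
    return PrecisionReport(
        mode=mode,
        n_datasets=int(len(counts)),
        n_repeats=int(counts.min()),
        rms_sd=rms_sd,
        rms_cv_pct=rms_cv,
        zero_mean_flags=flags,
    )
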