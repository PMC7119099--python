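"""Random-forest muscle segmentation with Gaussian histogram cleanup.

Each hand voxel is described by features of its neighbourhood (intensity,
Gaussian-smoothed intensity at two scales, local mean/SD at small radii,
gradient magnitude, distance to the hand boundary, normalized slice
position) and classified into muscle vs background by a random-forest
ensemble trained on labeled scans.  The union of muscle-classified voxels
is the muscle volume of interest (VOI).

The final cleanup fits a Gaussian to the intensity histogram of the VOI
and removes voxels outside mean +- 2 fitted SDs — this strips erroneously
included hypointense structures (ligaments, tendons) and hyperintense ones
(vessels) whose intensities sit in the tails.  The fitted Gaussian's
parameters (not the sample moments) define the retention window; if the
fit fails the sample median and 1.4826 x MAD are used instead.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from sklearn.ensemble import RandomForestClassifier

from .core import (
    AnalysisBounds,
    BinaryMask,
    ConfigError,
    DataError,
    InsufficientDataError,
    VolumeImage,
)

__all__ = [
    "FeatureConfig",
    "MuscleClassifier",
    "CleanupReport",
    "extract_voxel_features",
    "train_classifier",
    "classify_muscle",
    "gaussian_cleanup",
    "restrict_to_bounds",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Which neighbourhood features to compute per voxel.

    Radii are in voxels (cubic neighbourhoods of side ``2r+1``); smoothing
    scales are physical (mm) so they are anisotropy-aware.
    """

    mean_sd_radii: tuple[int, ...] = (1, 2)
    smoothing_scales_mm: tuple[float, ...] = (1.0, 2.0)
    include_gradient: bool = True
    include_slice_position: bool = True
    include_boundary_distance: bool = True

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.mean_sd_radii):
            raise ConfigError("radii must be >= 0")
        if any(s <= 0 for s in self.smoothing_scales_mm):
            raise ConfigError("smoothing scales must be > 0")
        if not self.feature_names():
            raise ConfigError("at least one feature must be enabled")

    def feature_names(self) -> tuple[str, ...]:
        names = ["intensity"]
        for s in self.smoothing_scales_mm:
            names.append(f"gauss_{s:g}mm")
        for r in self.mean_sd_radii:
            names += [f"mean_r{r}", f"sd_r{r}"]
        if self.include_gradient:
            names.append("grad_mag")
        if self.include_boundary_distance:
            names.append("boundary_dist_mm")
        if self.include_slice_position:
            names.append("slice_pos")
        return tuple(names)

    def fingerprint(self) -> str:
        return hashlib.sha256("|".join(self.feature_names()).encode()).hexdigest()[:16]


def extract_voxel_features(
    img: VolumeImage, hand: BinaryMask, cfg: FeatureConfig | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature table for every hand voxel.

    Returns ``(X, names)`` where ``X`` has one row per 1-voxel of ``hand``
    (in C order of the mask) and one column per feature.
    """
    cfg = cfg or FeatureConfig()
    if hand.count() == 0:
        raise DataError("empty hand mask")
    data = np.asarray(img.data, dtype=np.float64)
    dx, dy, dz = img.spacing
    sel = hand.as_bool()

    cols = [data[sel]]
    for s in cfg.smoothing_scales_mm:
        sig = (s / dz, s / dy, s / dx)
        cols.append(ndimage.gaussian_filter(data, sigma=sig, mode="nearest")[sel])
    for r in cfg.mean_sd_radii:
        size = 2 * r + 1
        m = ndimage.uniform_filter(data, size=size, mode="nearest")
        m2 = ndimage.uniform_filter(data * data, size=size, mode="nearest")
        var = np.clip(m2 - m * m, 0.0, None)
        cols.append(m[sel])
        cols.append(np.sqrt(var)[sel])
    if cfg.include_gradient:
        gz, gy, gx = np.gradient(data, dz, dy, dx)
        cols.append(np.sqrt(gx * gx + gy * gy + gz * gz)[sel])
    if cfg.include_boundary_distance:
        dist = ndimage.distance_transform_edt(sel, sampling=(dz, dy, dx))
        cols.append(dist[sel])
    if cfg.include_slice_position:
        ns = data.shape[0]
        zpos = np.broadcast_to(
            (np.arange(ns) / max(ns - 1, 1))[:, None, None], data.shape
        )
        cols.append(zpos[sel])

    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite feature values")
    return X, cfg.feature_names()


@dataclass
class MuscleClassifier:
    """Trained voxel classifier plus the feature fingerprint it expects."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    seed: int
    training_id: str = ""
    training_accuracy: float = float("nan")

    _FORMAT = "handquant-muscle-classifier-v1"

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format": self._FORMAT,
                "model": self.model,
                "feature_names": self.feature_names,
                "seed": self.seed,
                "training_id": self.training_id,
                "training_accuracy": self.training_accuracy,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MuscleClassifier":
        blob = joblib.load(path)
        if not isinstance(blob, dict) or blob.get("format") != cls._FORMAT:
            raise ConfigError(f"{path} is not a handquant muscle classifier")
        return cls(
            model=blob["model"],
            feature_names=tuple(blob["feature_names"]),
            seed=int(blob["seed"]),
            training_id=blob.get("training_id", ""),
            training_accuracy=float(blob.get("training_accuracy", float("nan"))),
        )


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...],
    n_trees: int = 100,
    seed: int = 0,
    max_depth: int | None = None,
    training_id: str = "",
) -> MuscleClassifier:
    """Train the random forest on labeled voxels.

    ``labels`` is a boolean/0-1 array (1 = muscle).  Both classes must be
    present.  Class weighting is balanced so the much larger background
    class does not dominate.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).astype(int).ravel()
    if features.shape[0] != labels.shape[0]:
        raise DataError("features and labels disagree in length")
    if features.shape[1] != len(feature_names):
        raise ConfigError("feature table does not match feature names")
    if np.unique(labels).size < 2:
        raise DataError("training needs both muscle and background voxels")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(features, labels)
    acc = float(rf.score(features, labels))
    return MuscleClassifier(
        model=rf,
        feature_names=tuple(feature_names),
        seed=seed,
        training_id=training_id,
        training_accuracy=acc,
    )


def classify_muscle(
    img: VolumeImage,
    hand: BinaryMask,
    clf: MuscleClassifier,
    cfg: FeatureConfig | None = None,
) -> BinaryMask:
    """Classify every hand voxel into muscle/background.

    The classifier's stored feature names must match the current feature
    configuration; a mismatch raises :class:`ConfigError` rather than
    silently predicting from misaligned columns.  The returned muscle mask
    is by construction a subset of the hand mask.
    """
    cfg = cfg or FeatureConfig()
    if tuple(clf.feature_names) != cfg.feature_names():
        raise ConfigError(
            f"feature fingerprint mismatch: classifier expects {clf.feature_names}, "
            f"config provides {cfg.feature_names()}"
        )
    X, _ = extract_voxel_features(img, hand, cfg)
    pred = clf.model.predict(X).astype(bool)
    out = np.zeros(img.data.shape, dtype=bool)
    out[hand.as_bool()] = pred
    return BinaryMask.like(img, out)


@dataclass(frozen=True)
class CleanupReport:
    """Outcome of the Gaussian histogram cleanup."""

    mean: float
    sd: float
    retained_fraction: float
    removed_count: int
    method: str              # "gaussian-fit" or "median-mad"
    degenerate: bool = False # sigma below tolerance; all voxels retained


def _fit_gaussian_to_histogram(values: np.ndarray) -> tuple[float, float, str]:
    """Gaussian fit of the intensity histogram (Freedman-Diaconis bins),
    falling back to median / 1.4826*MAD when the fit cannot be performed."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    robust_sd = 1.4826 * mad
    counts, edges = np.histogram(values, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(centers) < 4 or robust_sd == 0:
        return med, robust_sd, "median-mad"

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    try:
        popt, _ = curve_fit(
            gauss,
            centers,
            counts.astype(float),
            p0=(float(counts.max()), med, robust_sd),
            maxfev=5000,
        )
        mu, sig = float(popt[1]), abs(float(popt[2]))
        lo, hi = values.min(), values.max()
        if not np.isfinite(mu) or not np.isfinite(sig) or sig <= 0 or not (lo <= mu <= hi):
            raise RuntimeError("implausible fit")
        return mu, sig, "gaussian-fit"
    except Exception:
        return med, robust_sd, "median-mad"


def gaussian_cleanup(
    img: VolumeImage,
    muscle: BinaryMask,
    min_voxels: int = 50,
    sigma_tol: float = 1e-9,
) -> tuple[BinaryMask, CleanupReport]:
    """Remove VOI voxels outside mean +- 2 SD of the fitted histogram Gaussian.

    Raises :class:`InsufficientDataError` below ``min_voxels``.  A
    degenerate (near-zero) fitted SD retains all voxels and flags the
    report instead of removing everything.
    """
    n = muscle.count()
    if n == 0:
        raise DataError("empty muscle mask")
    if n < min_voxels:
        raise InsufficientDataError(
            f"only {n} muscle voxels; need >= {min_voxels} for a reliable fit"
        )
    sel = muscle.as_bool()
    values = np.asarray(img.data, dtype=np.float64)[sel]
    mu, sig, method = _fit_gaussian_to_histogram(values)

    if sig <= sigma_tol * max(abs(mu), 1.0):
        report = CleanupReport(
            mean=mu, sd=sig, retained_fraction=1.0, removed_count=0,
            method=method, degenerate=True,
        )
        return BinaryMask.like(img, sel.copy()), report

    keep = (values >= mu - 2.0 * sig) & (values <= mu + 2.0 * sig)
    out = np.zeros_like(sel)
    out[sel] = keep
    report = CleanupReport(
        mean=mu,
        sd=sig,
        retained_fraction=float(keep.mean()),
        removed_count=int(n - keep.sum()),
        method=method,
    )
    return BinaryMask.like(img, out), report


def restrict_to_bounds(mask: BinaryMask, bounds: AnalysisBounds) -> BinaryMask:
    """Zero all mask voxels outside the inclusive slice range."""
    bounds.validate_for(mask.data.shape[0])
    out = np.zeros_like(mask.data)
    sl = slice(bounds.proximal_slice, bounds.distal_slice + 1)
    out[sl] = mask.data[sl]
    return BinaryMask(data=out, spacing=mask.spacing, origin=mask.origin)
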