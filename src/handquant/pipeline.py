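"""Per-subject pipeline orchestration and cohort-level study runs.

``analyze_subject`` chains the stages in the order the method runs:
bias correction -> hand mask -> random-forest muscle classification ->
Gaussian cleanup -> restriction to the MCP-III bounds -> (optionally)
Dixon fat-fraction mapping, rigid VOI transfer and fat metrics.  The Dixon
pair is optional: scans without it yield metrics with the fat fields
absent, mirroring a cohort where Dixon imaging covers only a subset.

``run_subject``/``run_study`` wrap this with file I/O, a config-hashed
manifest, and deterministic per-stage seeds derived from one global seed,
so reruns with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AnalysisBounds,
    BinaryMask,
    ConfigError,
    DataError,
    HandQuantError,
    VolumeImage,
    read_volume,
    write_mask,
    write_volume,
)
from .dixon import (
    RegistrationConfig,
    compute_fat_fraction,
    register_rigid,
    transfer_voi,
)
from .muscle import (
    FeatureConfig,
    MuscleClassifier,
    classify_muscle,
    gaussian_cleanup,
    restrict_to_bounds,
)
from .preprocess import (
    BiasCorrectionConfig,
    HandMaskConfig,
    correct_bias_field,
    extract_hand_mask,
)
from .quantify import HandMetrics, compute_fat_metrics, compute_hand_metrics

logger = logging.getLogger("handquant")

__all__ = [
    "RunConfig",
    "analyze_subject",
    "run_subject",
    "run_study",
    "derive_seed",
    "train_on_phantoms",
    "train_from_labeled_dir",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """All stage configurations plus the global seed."""

    bias: BiasCorrectionConfig = field(default_factory=BiasCorrectionConfig)
    hand_mask: HandMaskConfig = field(default_factory=HandMaskConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    bounds: tuple[int, int] | None = None   # None: slices where the hand mask is nonempty
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            kwargs = {}
            if "bias" in raw:
                kwargs["bias"] = BiasCorrectionConfig(**raw["bias"])
            if "hand_mask" in raw:
                kwargs["hand_mask"] = HandMaskConfig(**raw["hand_mask"])
            if "features" in raw:
                feats = dict(raw["features"])
                for key in ("mean_sd_radii", "smoothing_scales_mm"):
                    if key in feats:
                        feats[key] = tuple(feats[key])
                kwargs["features"] = FeatureConfig(**feats)
            if "registration" in raw:
                kwargs["registration"] = RegistrationConfig(**raw["registration"])
            if "bounds" in raw and raw["bounds"] is not None:
                kwargs["bounds"] = tuple(int(x) for x in raw["bounds"])
            for key in ("seed", "log_level"):
                if key in raw:
                    kwargs[key] = raw[key]
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad run config {path}: {exc}") from exc


def _auto_bounds(hand: BinaryMask) -> AnalysisBounds:
    nonempty = np.flatnonzero(hand.data.any(axis=(1, 2)))
    return AnalysisBounds(int(nonempty[0]), int(nonempty[-1]))


def analyze_subject(
    t1: VolumeImage,
    clf: MuscleClassifier,
    cfg: RunConfig | None = None,
    water: VolumeImage | None = None,
    fat: VolumeImage | None = None,
    scan_id: str = "",
) -> tuple[HandMetrics, dict]:
    """Run the full per-subject analysis in memory.

    Returns ``(metrics, artifacts)`` where ``artifacts`` holds the
    intermediate images/masks and stage reports.  The Dixon stage runs only
    when both water and fat images are given.
    """
    cfg = cfg or RunConfig()
    art: dict = {}
    stage = "bias-correction"
    try:
        corrected, bias_field = correct_bias_field(t1, cfg.bias)
        art["corrected"], art["bias_field"] = corrected, bias_field

        stage = "hand-mask"
        hand = extract_hand_mask(corrected, cfg.hand_mask)
        art["hand_mask"] = hand

        stage = "muscle-classification"
        muscle_raw = classify_muscle(corrected, hand, clf, cfg.features)

        stage = "gaussian-cleanup"
        muscle, cleanup = gaussian_cleanup(corrected, muscle_raw)
        art["muscle_mask"], art["cleanup"] = muscle, cleanup

        stage = "quantification"
        bounds = (
            AnalysisBounds(*cfg.bounds) if cfg.bounds is not None else _auto_bounds(hand)
        )
        metrics = compute_hand_metrics(hand, muscle, bounds, scan_id=scan_id)

        if water is not None and fat is not None:
            stage = "fat-fraction"
            ff = compute_fat_fraction(water, fat)
            art["fat_fraction"] = ff
            stage = "registration"
            transform, reg_info = register_rigid(corrected, hand, water, cfg.registration)
            art["transform"], art["registration"] = transform, reg_info
            stage = "voi-transfer"
            muscle_ff = transfer_voi(muscle, transform, ff)
            art["muscle_on_ff"] = muscle_ff
            stage = "fat-metrics"
            v_f, v_f_rel = compute_fat_metrics(ff, muscle_ff)
            metrics = HandMetrics(
                v_h=metrics.v_h,
                v_m=metrics.v_m,
                v_m_rel=metrics.v_m_rel,
                v_f=v_f,
                v_f_rel=v_f_rel,
                bounds=bounds,
                scan_id=scan_id,
            )
    except HandQuantError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    return metrics, art


def _metrics_json(metrics: HandMetrics, cfg: RunConfig) -> str:
    payload = {
        "metrics": metrics.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
    return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def run_subject(
    t1_path: str | Path,
    model_path: str | Path,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    water_path: str | Path | None = None,
    fat_path: str | Path | None = None,
    scan_id: str | None = None,
) -> HandMetrics:
    """File-based per-subject run: reads NIfTI inputs, writes artifacts,
    metrics JSON and a manifest into ``out_dir``."""
    cfg = cfg or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t1 = read_volume(t1_path)
    water = read_volume(water_path) if water_path else None
    fat = read_volume(fat_path) if fat_path else None
    if (water is None) != (fat is None):
        raise ConfigError("water and fat images must be given together")
    clf = MuscleClassifier.load(model_path)
    sid = scan_id if scan_id is not None else Path(t1_path).stem.split(".")[0]

    metrics, art = analyze_subject(t1, clf, cfg, water=water, fat=fat, scan_id=sid)

    write_volume(art["corrected"], out / "t1_corrected.nii.gz")
    write_volume(art["bias_field"], out / "bias_field.nii.gz")
    write_mask(art["hand_mask"], out / "hand_mask.nii.gz")
    write_mask(art["muscle_mask"], out / "muscle_mask.nii.gz")
    if "fat_fraction" in art:
        write_volume(art["fat_fraction"].image, out / "fat_fraction.nii.gz")
        write_mask(art["muscle_on_ff"], out / "muscle_on_ff.nii.gz")
        (out / "transform.json").write_text(
            json.dumps(art["transform"].to_dict(), sort_keys=True, indent=2) + "\n"
        )
    (out / "metrics.json").write_text(_metrics_json(metrics, cfg))
    manifest = {
        "scan_id": sid,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": {
            "t1": str(t1_path),
            "water": str(water_path) if water_path else None,
            "fat": str(fat_path) if fat_path else None,
            "model": str(model_path),
        },
        "cleanup": {
            "mean": art["cleanup"].mean,
            "sd": art["cleanup"].sd,
            "retained_fraction": art["cleanup"].retained_fraction,
            "method": art["cleanup"].method,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return metrics


def _training_rows(
    t1: VolumeImage,
    muscle_truth: BinaryMask,
    cfg: RunConfig,
    rng: np.random.Generator,
    max_per_class: int,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Feature rows + labels for one labeled scan, subsampled per class.

    Features are computed on the bias-corrected image inside the pipeline's
    own hand mask, so the training distribution matches prediction time.
    """
    from .muscle import extract_voxel_features

    corrected, _ = correct_bias_field(t1, cfg.bias)
    hand = extract_hand_mask(corrected, cfg.hand_mask)
    X, names = extract_voxel_features(corrected, hand, cfg.features)
    y = muscle_truth.as_bool()[hand.as_bool()].astype(int)
    keep = np.zeros(len(y), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) > max_per_class:
            idx = rng.choice(idx, size=max_per_class, replace=False)
        keep[idx] = True
    return X[keep], y[keep], names


def train_on_phantoms(
    phantom_seeds,
    cfg: RunConfig | None = None,
    n_trees: int = 100,
    seed: int = 0,
    max_per_class: int = 20000,
    spec=None,
):
    """Train the muscle classifier on synthetic phantoms.

    The phantoms' true muscle labels stand in for manual segmentations.
    Returns a :class:`~handquant.muscle.MuscleClassifier`.
    """
    from dataclasses import replace as _replace

    from .muscle import train_classifier
    from .synthetic import PhantomSpec, generate_hand_phantom

    cfg = cfg or RunConfig()
    base = spec or PhantomSpec()
    rng = np.random.default_rng(derive_seed(seed, "training-subsample"))
    Xs, ys = [], []
    names = None
    for s in phantom_seeds:
        t1, _, _, truth = generate_hand_phantom(_replace(base, seed=int(s)))
        X, y, names = _training_rows(t1, truth.muscle_mask(), cfg, rng, max_per_class)
        Xs.append(X)
        ys.append(y)
    return train_classifier(
        np.vstack(Xs),
        np.concatenate(ys),
        names,
        n_trees=n_trees,
        seed=derive_seed(seed, "random-forest"),
        training_id=f"phantoms:{','.join(str(s) for s in phantom_seeds)}",
    )


def train_from_labeled_dir(
    labeled_dir: str | Path,
    cfg: RunConfig | None = None,
    n_trees: int = 100,
    seed: int = 0,
    max_per_class: int = 20000,
):
    """Train from subject directories holding ``t1.nii.gz`` + ``muscle.nii.gz``
    (a binary manual muscle segmentation on the T1 grid)."""
    from .core import read_mask
    from .muscle import train_classifier

    cfg = cfg or RunConfig()
    root = Path(labeled_dir)
    pairs = sorted(
        p for p in root.iterdir()
        if (p / "t1.nii.gz").exists() and (p / "muscle.nii.gz").exists()
    )
    if not pairs:
        raise DataError(f"no labeled subjects (t1.nii.gz + muscle.nii.gz) under {root}")
    rng = np.random.default_rng(derive_seed(seed, "training-subsample"))
    Xs, ys = [], []
    names = None
    for p in pairs:
        t1 = read_volume(p / "t1.nii.gz")
        muscle = read_mask(p / "muscle.nii.gz")
        X, y, names = _training_rows(t1, muscle, cfg, rng, max_per_class)
        Xs.append(X)
        ys.append(y)
    return train_classifier(
        np.vstack(Xs),
        np.concatenate(ys),
        names,
        n_trees=n_trees,
        seed=derive_seed(seed, "random-forest"),
        training_id=f"dir:{root.name}:{len(pairs)}",
    )


def run_study(
    subjects_dir: str | Path,
    model_path: str | Path,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Analyze every subject directory under ``subjects_dir``.

    Each subject directory must contain ``t1.nii.gz`` and may contain
    ``water.nii.gz`` + ``fat.nii.gz``.  Per-subject failures are logged and
    excluded, with the exclusion list written to the study manifest.
    Returns the cohort table (volumes converted to cm^3), joined with
    ``demographics`` on ``id`` when given.
    """
    cfg = cfg or RunConfig()
    root = Path(subjects_dir)
    subject_dirs = sorted(p for p in root.iterdir() if (p / "t1.nii.gz").exists())
    if not subject_dirs:
        raise DataError(f"no subject directories with t1.nii.gz under {root}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows, excluded = [], []
    for sd in subject_dirs:
        water = sd / "water.nii.gz"
        fat = sd / "fat.nii.gz"
        try:
            m = run_subject(
                sd / "t1.nii.gz",
                model_path,
                out / sd.name,
                cfg,
                water_path=water if water.exists() else None,
                fat_path=fat if fat.exists() else None,
                scan_id=sd.name,
            )
        except HandQuantError as exc:
            logger.warning("subject %s excluded: %s", sd.name, exc)
            excluded.append({"id": sd.name, "reason": str(exc)})
            continue
        rows.append(
            {
                "id": sd.name,
                "vh": m.v_h / 1000.0,   # mm^3 -> cm^3
                "vm": m.v_m / 1000.0,
                "vmrel": m.v_m_rel,
                "vf": (m.v_f / 1000.0) if m.v_f is not None else np.nan,
                "vfrel": m.v_f_rel if m.v_f_rel is not None else np.nan,
            }
        )
    cohort = pd.DataFrame(rows)
    if demographics is not None and not cohort.empty:
        cohort = demographics.merge(cohort, on="id", how="inner")
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": len(subject_dirs),
        "n_included": len(rows),
        "excluded": excluded,
    }
    (out / "study_manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return cohort
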