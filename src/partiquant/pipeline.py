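"""End-to-end experiment orchestration: simulate -> mask -> segment ->
quantify -> stats -> report.

A single :class:`ExperimentConfig` drives the whole run with explicit
seeds throughout; identical configs give byte-identical CSV outputs.  The
slow stage (simulation + segmentation + quantification) is cached on the
hash of the config sections it depends on, so changing only the statistics
settings re-uses the density table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .conditions import (
    DEFAULT_CONDITIONS,
    DEFAULT_RECOVERY_PARAMS,
    LABEL_CONTENT_MG,
    ConditionSpec,
    MethodRecoveryParams,
    MorphologySpec,
)
from .quantify import compute_density, filter_to_valid_area, segment_to_detections
from .recovery import (
    anova_by_bin,
    build_report,
    pairwise_welch,
    summarize_method,
)
from .regions import (
    classify_valid_area,
    extract_pixel_features,
    region_mask_from_truth,
    threshold_artifacts,
    train_region_classifier,
)
from .segmentation import (
    LEARNER1_CONFIG,
    LEARNER2_CONFIG,
    active_learning_loop,
    predict_mask,
    stitch_patches,
    tile_slide,
)
from .synthetic import (
    generate_measurements,
    generate_slide,
    ground_truth_region_labels,
    measurements_to_frame,
)


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("invalid experiment config:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class ExperimentConfig:
    conditions: Dict[str, ConditionSpec] = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))
    recovery_params: Dict[str, MethodRecoveryParams] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_PARAMS)
    )
    slides_per_condition: int = 3
    mpp: float = 1.0
    slide_size_px: Tuple[int, int] = (1024, 1024)
    segmentation: str = "oracle"  # "oracle" | "learned"
    patch_size: int = 256
    downsample: int = 2
    al_rounds: int = 2
    al_batch: int = 4
    al_direction: str = "high"
    al_initial_fraction: float = 0.1
    min_overlap: float = 0.5
    label_content_mg: float = LABEL_CONTENT_MG
    seed: int = 0

    def section_hash(self, which: str = "imaging") -> str:
        d = _config_dict(self)
        if which == "imaging":
            d.pop("label_content_mg", None)
            d.pop("recovery_params", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["conditions"] = {
        k: {
            "morphologies": {m: asdict(s) for m, s in v.morphologies.items()},
            "bubble_density_per_mm2": v.bubble_density_per_mm2,
            "edge_artifact": v.edge_artifact,
        }
        for k, v in cfg.conditions.items()
    }
    d["recovery_params"] = {k: asdict(v) for k, v in cfg.recovery_params.items()}
    d["slide_size_px"] = list(cfg.slide_size_px)
    return d


_KNOWN_KEYS = {
    "conditions", "recovery_params", "slides_per_condition", "mpp", "slide_size_px",
    "segmentation", "patch_size", "downsample", "al_rounds", "al_batch", "al_direction",
    "al_initial_fraction", "min_overlap", "label_content_mg", "seed",
}


def validate_config(raw: Optional[dict]) -> ExperimentConfig:
    """Validate a raw (YAML-loaded) document, aggregating all errors."""
    raw = dict(raw or {})
    errors: List[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key: {key}")

    conditions: Dict[str, ConditionSpec] = dict(DEFAULT_CONDITIONS)
    if "conditions" in raw:
        conditions = {}
        for name, doc in raw["conditions"].items():
            try:
                morphs = {
                    m: MorphologySpec(**spec) for m, spec in doc.get("morphologies", {}).items()
                }
                conditions[name] = ConditionSpec(
                    name=name,
                    morphologies=morphs,
                    bubble_density_per_mm2=doc.get("bubble_density_per_mm2", 0.3),
                    edge_artifact=doc.get("edge_artifact", True),
                )
            except (TypeError, ValueError) as e:
                errors.append(f"conditions.{name}: {e}")

    recovery = dict(DEFAULT_RECOVERY_PARAMS)
    if "recovery_params" in raw:
        recovery = {}
        for name, doc in raw["recovery_params"].items():
            try:
                recovery[name] = MethodRecoveryParams(**doc)
            except (TypeError, ValueError) as e:
                errors.append(f"recovery_params.{name}: {e}")

    def _num(key, default, lo=None, hi=None, integer=False):
        v = raw.get(key, default)
        if integer and not isinstance(v, (int, np.integer)):
            errors.append(f"{key}: must be an integer, got {v!r}")
            return default
        try:
            v = int(v) if integer else float(v)
        except (TypeError, ValueError):
            errors.append(f"{key}: not a number: {v!r}")
            return default
        if lo is not None and v < lo:
            errors.append(f"{key}: must be >= {lo}, got {v}")
        if hi is not None and v > hi:
            errors.append(f"{key}: must be <= {hi}, got {v}")
        return v

    slides = _num("slides_per_condition", 3, lo=1, integer=True)
    mpp = _num("mpp", 1.0, lo=1e-6)
    size = raw.get("slide_size_px", (1024, 1024))
    try:
        size = (int(size[0]), int(size[1]))
        if min(size) < 32:
            errors.append(f"slide_size_px: dimensions must be >= 32, got {size}")
    except (TypeError, ValueError, IndexError):
        errors.append(f"slide_size_px: expected a pair of integers, got {size!r}")
        size = (1024, 1024)
    segmentation = raw.get("segmentation", "oracle")
    if segmentation not in ("oracle", "learned"):
        errors.append(f"segmentation: must be 'oracle' or 'learned', got {segmentation!r}")
    direction = raw.get("al_direction", "high")
    if direction not in ("high", "low"):
        errors.append(f"al_direction: must be 'high' or 'low', got {direction!r}")
    cfg = ExperimentConfig(
        conditions=conditions,
        recovery_params=recovery,
        slides_per_condition=slides,
        mpp=mpp,
        slide_size_px=size,
        segmentation=segmentation,
        patch_size=_num("patch_size", 256, lo=1, integer=True),
        downsample=_num("downsample", 2, lo=1, integer=True),
        al_rounds=_num("al_rounds", 2, lo=0, integer=True),
        al_batch=_num("al_batch", 4, lo=1, integer=True),
        al_direction=direction,
        al_initial_fraction=_num("al_initial_fraction", 0.1, lo=0.0, hi=1.0),
        min_overlap=_num("min_overlap", 0.5, lo=1e-9, hi=1.0),
        label_content_mg=_num("label_content_mg", LABEL_CONTENT_MG, lo=1e-9),
        seed=_num("seed", 0, lo=0, integer=True),
    )
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    return validate_config(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config_hash: str
    imaging_hash: str
    stages: Dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _slide_seed(base: int, cond_index: int, slide_index: int) -> int:
    return (base * 7919 + cond_index * 101 + slide_index) % (2**31 - 1)


def _learned_particle_mask(image, truth, cfg: ExperimentConfig, seed: int) -> np.ndarray:
    """Patch-wise dual-learner segmentation with a short annotation loop."""
    patches = tile_slide(image, cfg.patch_size, cfg.downsample)
    truth_patches = tile_slide(
        type(image)(truth.particle_mask.astype(np.uint8), image.mpp), cfg.patch_size, cfg.downsample
    )
    truth_by_id = {p.patch_id: p.pixels.astype(bool) for p in truth_patches}
    rng = np.random.default_rng(seed)
    n_init = max(1, round(cfg.al_initial_fraction * len(patches)))
    order = rng.permutation(len(patches))
    initial, pool = [], []
    for rank, idx in enumerate(order):
        p = patches[idx]
        if rank < n_init:
            p.annotation = truth_by_id[p.patch_id] & p.valid
            initial.append(p)
        else:
            pool.append(p)
    if not any((p.annotation & p.valid).any() for p in initial):
        # ensure the initial set contains particles
        for p in pool:
            if (truth_by_id[p.patch_id] & p.valid).any():
                p.annotation = truth_by_id[p.patch_id] & p.valid
                initial.append(p)
                pool.remove(p)
                break
    oracle = lambda p: truth_by_id[p.patch_id] & p.valid
    l1, _, _ = active_learning_loop(
        initial, pool, oracle, rounds=cfg.al_rounds, batch=cfg.al_batch,
        direction=cfg.al_direction, seed=seed,
    )
    masks = {p.patch_id: predict_mask(l1, p) for p in patches}
    ds_shape = image.pixels[:: cfg.downsample, :: cfg.downsample].shape
    ds_mask = stitch_patches(masks, patches, ds_shape)
    # drop isolated speck predictions, then upsample back to slide
    # resolution (nearest neighbour)
    from skimage.morphology import remove_small_objects

    ds_mask = remove_small_objects(ds_mask, max_size=3)
    full = np.kron(ds_mask, np.ones((cfg.downsample, cfg.downsample), dtype=bool))
    return full[: image.pixels.shape[0], : image.pixels.shape[1]]


def _learned_region_mask(image, truth, seed: int):
    feats = extract_pixel_features(image)
    labels = ground_truth_region_labels(truth)
    rng = np.random.default_rng(seed)
    ann = np.zeros_like(labels)
    keep = rng.random(labels.shape) < 0.2
    ann[keep] = labels[keep]
    if not {1, 2}.issubset(set(np.unique(ann[ann > 0]).tolist())):
        return region_mask_from_truth(truth)  # degenerate slide: nothing to learn
    clf = train_region_classifier(feats, ann, seed=seed, n_estimators=50, max_train_pixels=20_000)
    prelim = threshold_artifacts(image)
    return classify_valid_area(image, clf, prelim, features=feats)


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> RunManifest:
    """Run the full experiment and write all report artifacts.

    Writes densities.csv, measurements.csv, recovery.csv, pairwise.csv,
    anova.csv, report.md and manifest.json under ``out_dir``.  The imaging
    stage is cached on its config-section hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.section_hash("full"), config.section_hash("imaging"))

    densities_path = out / "densities.csv"
    cache_ok = False
    manifest_path = out / "manifest.json"
    if densities_path.exists() and manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            cache_ok = old.get("imaging_hash") == manifest.imaging_hash
        except json.JSONDecodeError:
            cache_ok = False

    if cache_ok:
        densities = pd.read_csv(densities_path)
        manifest.stages["imaging"] = {"status": "cached"}
    else:
        frames = []
        for ci, name in enumerate(sorted(config.conditions)):
            spec = config.conditions[name]
            for si in range(config.slides_per_condition):
                seed = _slide_seed(config.seed, ci, si)
                image, truth = generate_slide(spec, config.mpp, config.slide_size_px, seed)
                if config.segmentation == "oracle":
                    region = region_mask_from_truth(truth)
                    mask = truth.particle_mask
                else:
                    region = _learned_region_mask(image, truth, seed)
                    mask = _learned_particle_mask(image, truth, config, seed)
                detections = segment_to_detections(mask, config.mpp)
                detections = filter_to_valid_area(detections, region, config.min_overlap)
                dens = compute_density(detections, region, name)
                dens.insert(1, "slide", si)
                frames.append(dens)
        densities = pd.concat(frames, ignore_index=True)
        densities.to_csv(densities_path, index=False)
        manifest.stages["imaging"] = {"status": "computed"}

    measurements = generate_measurements(config.recovery_params, seed=config.seed)
    meas_frame = measurements_to_frame(measurements)
    meas_path = out / "measurements.csv"
    meas_frame.to_csv(meas_path, index=False)

    summaries = {
        m: summarize_method(
            [x for x in measurements if x.method == m], config.label_content_mg
        )
        for m in sorted(config.recovery_params)
    }
    pairwise = pairwise_welch(summaries, field="sum")
    report = build_report(summaries, pairwise, densities)

    paths = {"densities.csv": densities_path, "measurements.csv": meas_path}
    report["recovery"].to_csv(out / "recovery.csv", index=False)
    paths["recovery.csv"] = out / "recovery.csv"
    pairwise.to_csv(out / "pairwise.csv", index=False)
    paths["pairwise.csv"] = out / "pairwise.csv"
    if "anova" in report:
        report["anova"].to_csv(out / "anova.csv", index=False)
        paths["anova.csv"] = out / "anova.csv"
    (out / "report.md").write_text(report["markdown"])
    paths["report.md"] = out / "report.md"
    if "density" in report:
        # figure is written for inspection but kept out of the checksum
        # manifest (image encoding is not guaranteed byte-stable)
        from .plots import plot_density_bars

        plot_density_bars(report["density"], out / "densities.png")

    manifest.stages["stats"] = {"status": "computed"}
    manifest.stages["outputs"] = {name: _sha256(p) for name, p in sorted(paths.items())}
    manifest_path.write_text(manifest.to_json())
    return manifest
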