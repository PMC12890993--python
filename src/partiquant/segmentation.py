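"""Dual-learner particle segmentation with agreement-ranked active learning.

Two independently configured per-pixel segmenters are trained on the same
annotated patches; unannotated patches are then prioritised for oracle
annotation by the Intersection-over-Union (IoU) agreement between the two
learners' predictions.  Ranking by HIGH agreement first follows the source
protocol this package models (model-assisted annotation of confident
patches); the classical uncertainty-sampling direction (low agreement
first) is available behind a flag.

The default learner is a random-forest pixel classifier over a multi-scale
filter-bank feature stack; the two ensemble members differ in feature
scales, tree randomisation and seed, standing in for two differently
backboned convolutional networks.  Any object implementing
``fit(patches, seed)`` / ``predict(patch)`` can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier

from .regions import extract_pixel_features
from .synthetic import SlideImage


@dataclass
class Patch:
    """A fixed-size tile of a (possibly downsampled) slide raster.

    ``origin`` is the (row, col) offset of the tile in the downsampled
    raster; ``valid`` marks pixels inside the original raster (False in the
    zero-padded margin).  ``annotation`` is an optional binary particle
    mask of the same shape.
    """

    patch_id: int
    pixels: np.ndarray
    origin: Tuple[int, int]
    downsample: int
    valid: np.ndarray
    annotation: Optional[np.ndarray] = None

    @property
    def slide_origin(self) -> Tuple[int, int]:
        """(row, col) of the tile origin in full-resolution slide coords."""
        return (self.origin[0] * self.downsample, self.origin[1] * self.downsample)


def tile_slide(
    image: SlideImage,
    patch_size: int = 2048,
    downsample: int = 4,
    annotation: Optional[np.ndarray] = None,
) -> List[Patch]:
    """Tile a slide into zero-padded fixed-size patches.

    The raster is downsampled by strided subsampling, then partitioned into
    ceil(H/p) x ceil(W/p) tiles; edge tiles are zero-padded to full size
    with a validity mask.  Reassembling the tiles reproduces the
    downsampled raster exactly.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    ds = image.pixels[::downsample, ::downsample]
    ann_ds = annotation[::downsample, ::downsample] if annotation is not None else None
    h, w = ds.shape
    patches: List[Patch] = []
    pid = 0
    for r0 in range(0, h, patch_size):
        for c0 in range(0, w, patch_size):
            tile = np.zeros((patch_size, patch_size), dtype=ds.dtype)
            valid = np.zeros((patch_size, patch_size), dtype=bool)
            block = ds[r0 : r0 + patch_size, c0 : c0 + patch_size]
            tile[: block.shape[0], : block.shape[1]] = block
            valid[: block.shape[0], : block.shape[1]] = True
            ann = None
            if ann_ds is not None:
                ann = np.zeros((patch_size, patch_size), dtype=bool)
                ab = ann_ds[r0 : r0 + patch_size, c0 : c0 + patch_size]
                ann[: ab.shape[0], : ab.shape[1]] = ab.astype(bool)
            patches.append(Patch(pid, tile, (r0, c0), downsample, valid, ann))
            pid += 1
    return patches


def stitch_patches(masks: Dict[int, np.ndarray], patches: Sequence[Patch], shape: Tuple[int, int]) -> np.ndarray:
    """Reassemble per-patch masks into a downsampled-raster mask."""
    out = np.zeros(shape, dtype=bool)
    for p in patches:
        if p.patch_id not in masks:
            continue
        m = masks[p.patch_id]
        r0, c0 = p.origin
        hh = min(shape[0] - r0, m.shape[0])
        ww = min(shape[1] - c0, m.shape[1])
        out[r0 : r0 + hh, c0 : c0 + ww] |= m[:hh, :ww]
    return out


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters distinguishing one ensemble member."""

    name: str = "learner-1"
    scales: Tuple[float, ...] = (1.0, 2.0, 4.0)
    n_estimators: int = 40
    kind: str = "rf"  # "rf" | "extra"
    max_train_pixels_per_patch: int = 3000
    threshold: float = 0.5


#: two deliberately different default configurations, one per ensemble member
LEARNER1_CONFIG = LearnerConfig(name="learner-1", scales=(1.0, 2.0, 4.0), kind="rf")
LEARNER2_CONFIG = LearnerConfig(name="learner-2", scales=(1.0, 3.0, 6.0), kind="extra")


@dataclass
class Learner:
    """A trained per-pixel binary segmenter (one ensemble member)."""

    config: LearnerConfig
    seed: int
    model: Optional[object] = None

    @property
    def is_trained(self) -> bool:
        return self.model is not None

    def _features(self, patch: Patch) -> np.ndarray:
        img = SlideImage(patch.pixels, 1.0)
        return extract_pixel_features(img, self.config.scales)


def train_learner(
    patches: Sequence[Patch],
    config: LearnerConfig = LEARNER1_CONFIG,
    seed: int = 0,
) -> Learner:
    """Train one ensemble member on the annotated patches.

    Pixels are subsampled per patch (all positives up to the budget,
    negatives to fill it); training is deterministic for a fixed seed.
    """
    annotated = [p for p in patches if p.annotation is not None]
    if not annotated:
        raise ValueError("at least one annotated patch is required")
    total_pos = sum(int((p.annotation & p.valid).sum()) for p in annotated)
    if total_pos == 0:
        raise ValueError("no positive (particle) pixels in any annotation")
    rng = np.random.default_rng(seed)
    learner = Learner(config, seed)
    Xs, ys = [], []
    for p in annotated:
        feats = learner._features(p)
        pos = np.flatnonzero((p.annotation & p.valid).ravel())
        neg = np.flatnonzero((~p.annotation & p.valid).ravel())
        budget = config.max_train_pixels_per_patch
        n_pos = min(pos.size, budget // 2)
        if pos.size > n_pos:
            pos = rng.choice(pos, n_pos, replace=False)
        n_neg = min(neg.size, budget - n_pos)
        if neg.size > n_neg:
            neg = rng.choice(neg, n_neg, replace=False)
        idx = np.concatenate([pos, neg])
        idx.sort()
        flat = feats.reshape(-1, feats.shape[-1])
        Xs.append(flat[idx])
        ys.append(p.annotation.ravel()[idx])
    X = np.concatenate(Xs)
    y = np.concatenate(ys).astype(np.uint8)
    cls = RandomForestClassifier if config.kind == "rf" else ExtraTreesClassifier
    model = cls(n_estimators=config.n_estimators, random_state=seed, n_jobs=1)
    model.fit(X, y)
    learner.model = model
    return learner


def predict_mask(learner: Learner, patch: Patch) -> np.ndarray:
    """Predict a binary particle mask for one patch; padding is background."""
    if not learner.is_trained:
        raise ValueError("learner has not been trained")
    feats = learner._features(patch)
    flat = feats.reshape(-1, feats.shape[-1])
    proba = learner.model.predict_proba(flat)
    classes = list(learner.model.classes_)
    p1 = proba[:, classes.index(1)] if 1 in classes else np.zeros(flat.shape[0])
    mask = (p1 >= learner.config.threshold).reshape(patch.pixels.shape)
    mask &= patch.valid
    return mask


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over Union of two binary masks.

    Two empty masks agree perfectly (IoU = 1); this convention matters
    because it ranks blank patches at the top of a high-agreement ordering.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


@dataclass
class AgreementRanking:
    """Patches ordered by inter-learner IoU (descending, ties by id)."""

    entries: List[Tuple[int, float]]

    def top(self, k: int, direction: str = "high") -> List[int]:
        order = self.entries if direction == "high" else self.entries[::-1]
        return [pid for pid, _ in order[:k]]


def rank_patches_by_agreement(
    learner1: Learner, learner2: Learner, pool: Sequence[Patch]
) -> AgreementRanking:
    """Rank unannotated patches by IoU agreement between the two learners."""
    if not (learner1.is_trained and learner2.is_trained):
        raise ValueError("both learners must be trained before ranking")
    scores = []
    for p in pool:
        m1 = predict_mask(learner1, p)
        m2 = predict_mask(learner2, p)
        scores.append((p.patch_id, iou(m1, m2)))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return AgreementRanking(scores)


def active_learning_loop(
    initial: Sequence[Patch],
    pool: Sequence[Patch],
    oracle: Callable[[Patch], np.ndarray],
    rounds: int = 4,
    batch: int = 5,
    direction: str = "high",
    config1: LearnerConfig = LEARNER1_CONFIG,
    config2: LearnerConfig = LEARNER2_CONFIG,
    seed: int = 0,
) -> Tuple[Learner, Learner, pd.DataFrame]:
    """Run the agreement-ranked annotation loop.

    Each round: rank the pool by inter-learner agreement, send the
    ``batch`` highest- (or lowest-) agreement patches to the oracle, move
    them to the training set and retrain both learners.  Returns the final
    learners and a log with one row per annotated patch
    (round, patch_id, iou_at_selection).
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if batch < 1:
        raise ValueError("batch must be >= 1")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    train = list(initial)
    pool = list(pool)
    l1 = train_learner(train, config1, seed)
    l2 = train_learner(train, config2, seed + 1)
    log: List[dict] = []
    for rnd in range(1, rounds + 1):
        if not pool:
            break
        ranking = rank_patches_by_agreement(l1, l2, pool)
        chosen = set(ranking.top(batch, direction))
        by_id = {p.patch_id: p for p in pool}
        scores = dict(ranking.entries)
        for pid in sorted(chosen):
            p = by_id[pid]
            p.annotation = np.asarray(oracle(p), dtype=bool)
            train.append(p)
            log.append({"round": rnd, "patch_id": pid, "iou_at_selection": scores[pid]})
        pool = [p for p in pool if p.patch_id not in chosen]
        l1 = train_learner(train, config1, seed)
        l2 = train_learner(train, config2, seed + 1)
    return l1, l2, pd.DataFrame(log, columns=["round", "patch_id", "iou_at_selection"])
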