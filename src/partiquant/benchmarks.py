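"""Self-validation experiments on the synthetic study conditions.

These drivers exercise the whole pipeline against the generator's known
ground truth: per-bin density recovery against the configured Poisson
rates, the qualitative per-bin ordering of the default conditions,
active-learning improvement on held-out patches, and the type-I error of
the Welch test under a null with unequal variances.  They are used by the
test suite and the reproduction script; raster sizes are arguments so the
experiments scale from quick checks to full runs.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conditions import DEFAULT_CONDITIONS, ConditionSpec, MorphologySpec
from .quantify import BIN_LABELS, compute_density, filter_to_valid_area, segment_to_detections
from .regions import region_mask_from_truth
from .segmentation import (
    LEARNER1_CONFIG,
    LEARNER2_CONFIG,
    Patch,
    active_learning_loop,
    iou,
    predict_mask,
    train_learner,
)
from .synthetic import generate_slide


def quantify_slide_oracle(
    spec: ConditionSpec, mpp: float, size_px: Tuple[int, int], seed: int
) -> pd.DataFrame:
    """Generate one slide and quantify it through ground-truth masks."""
    _, truth = generate_slide(spec, mpp, size_px, seed)
    region = region_mask_from_truth(truth)
    detections = segment_to_detections(truth.particle_mask, mpp)
    detections = filter_to_valid_area(detections, region)
    return compute_density(detections, region, spec.name)


def density_recovery_experiment(
    spec: ConditionSpec,
    mpp: float = 2.0,
    size_px: Tuple[int, int] = (1000, 1000),
    seed: int = 0,
) -> pd.DataFrame:
    """Compare recovered per-bin counts with the configured Poisson rates.

    The tolerance per bin is max(3*sqrt(lambda), 3) counts: three Poisson
    standard deviations, floored at three counts because the 3-sigma band
    is narrower than one count for near-empty bins.
    """
    dens = quantify_slide_oracle(spec, mpp, size_px, seed)
    area = float(dens["valid_area_mm2"].iloc[0])
    lam = spec.expected_bin_densities() * area
    out = dens[["condition", "bin", "count"]].copy()
    out["expected_count"] = lam
    out["tolerance"] = np.maximum(3.0 * np.sqrt(lam), 3.0)
    out["abs_error"] = (out["count"] - out["expected_count"]).abs()
    out["within_tolerance"] = out["abs_error"] <= out["tolerance"]
    return out


def ordering_experiment(
    conditions: Optional[Mapping[str, ConditionSpec]] = None,
    n_seeds: int = 10,
    mpp: float = 2.0,
    size_px: Tuple[int, int] = (700, 700),
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, bool]]:
    """Pooled per-bin densities across seeds and the qualitative ordering.

    Returns the pooled density table (counts and areas summed over seeds)
    and the five ordering checks: A maximal in "<100", B maximal in
    ">500", C maximal in combined 100-500, D minimal (non-strict; ties at
    zero counts are possible in sparse bins) in every bin among A-D, and
    the blank's total density below 1% of the sparsest non-blank
    condition's.
    """
    conditions = dict(conditions or DEFAULT_CONDITIONS)
    frames = []
    for name in sorted(conditions):
        for s in range(n_seeds):
            dens = quantify_slide_oracle(conditions[name], mpp, size_px, seed * 1009 + s)
            dens.insert(1, "seed", s)
            frames.append(dens)
    all_dens = pd.concat(frames, ignore_index=True)
    pooled = (
        all_dens.groupby(["condition", "bin"], sort=False)
        .agg(count=("count", "sum"), area=("valid_area_mm2", "sum"))
        .reset_index()
    )
    pooled["density_per_mm2"] = pooled["count"] / pooled["area"]
    dens_of = lambda c, b: float(
        pooled.loc[(pooled["condition"] == c) & (pooled["bin"] == b), "density_per_mm2"].iloc[0]
    )
    non_blank = [c for c in ("A", "B", "C", "D") if c in conditions]
    checks = {
        "A_max_small": dens_of("A", "<100") > max(dens_of(c, "<100") for c in non_blank if c != "A"),
        "B_max_large": dens_of("B", ">500") > max(dens_of(c, ">500") for c in non_blank if c != "B"),
        "C_max_mid": (dens_of("C", "100-250") + dens_of("C", "250-500"))
        > max(dens_of(c, "100-250") + dens_of(c, "250-500") for c in non_blank if c != "C"),
        "D_min_all_bins": all(
            dens_of("D", b) <= min(dens_of(c, b) for c in non_blank if c != "D") for b in BIN_LABELS
        ),
    }
    if "blank" in conditions:
        blank_total = sum(dens_of("blank", b) for b in BIN_LABELS)
        sparsest = min(sum(dens_of(c, b) for b in BIN_LABELS) for c in non_blank)
        checks["blank_near_zero"] = blank_total < 0.01 * sparsest
    return pooled, checks


#: particle mix used for the active-learning patch experiments: moderate
#: densities of all three morphologies at patch-scale sizes, with some air
#: bubbles for difficulty
AL_PATCH_CONDITION = ConditionSpec(
    name="al-patch",
    morphologies={
        "black_dot": MorphologySpec(80.0, 30.0, 1.5),
        "crystal": MorphologySpec(40.0, 60.0, 1.5),
        "cotton": MorphologySpec(40.0, 50.0, 1.5),
    },
    bubble_density_per_mm2=1.0,
    edge_artifact=False,
)


def make_patch_pool(
    n_patches: int,
    patch_px: int = 96,
    mpp: float = 2.0,
    seed: int = 0,
    spec: ConditionSpec = AL_PATCH_CONDITION,
    noise_sd: float = 35.0,
) -> Tuple[List[Patch], Dict[int, np.ndarray]]:
    """Independent single-patch slides with ground-truth masks.

    ``noise_sd`` adds extra zero-mean sensor noise on top of the rendered
    patches; without it the filter-bank learners segment the clean
    renderings perfectly from a handful of patches and the learning curve
    is flat.
    """
    patches: List[Patch] = []
    truths: Dict[int, np.ndarray] = {}
    noise_rng = np.random.default_rng(seed + 2**20)
    for pid in range(n_patches):
        image, truth = generate_slide(spec, mpp, (patch_px, patch_px), seed * 100_003 + pid)
        pixels = image.pixels
        if noise_sd > 0:
            pixels = np.clip(
                pixels.astype(float) + noise_rng.normal(0.0, noise_sd, pixels.shape), 0, 255
            ).astype(np.uint8)
        patches.append(Patch(pid, pixels, (0, 0), 1, np.ones((patch_px, patch_px), dtype=bool)))
        truths[pid] = truth.particle_mask
    return patches, truths


def heldout_mean_iou(learner, patches: Sequence[Patch], truths: Mapping[int, np.ndarray]) -> float:
    scores = [iou(predict_mask(learner, p), truths[p.patch_id]) for p in patches]
    return float(np.mean(scores))


def al_improvement_experiment(
    n_seeds: int = 10,
    pool_size: int = 45,
    n_initial: int = 5,
    n_heldout: int = 10,
    rounds: int = 4,
    batch: int = 5,
    patch_px: int = 96,
    mpp: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out segmentation IoU before vs after the annotation loop.

    One row per seed with the held-out mean IoU of the primary learner
    trained on the initial ~10% annotations and after the full
    agreement-ranked loop.
    """
    rows = []
    for s in range(n_seeds):
        run_seed = seed * 7919 + s
        patches, truths = make_patch_pool(
            n_initial + pool_size + n_heldout, patch_px, mpp, run_seed
        )
        initial = patches[:n_initial]
        pool = patches[n_initial : n_initial + pool_size]
        heldout = patches[n_initial + pool_size :]
        for p in initial:
            p.annotation = truths[p.patch_id]
        before = train_learner(initial, LEARNER1_CONFIG, run_seed)
        iou_before = heldout_mean_iou(before, heldout, truths)
        l1, _, _ = active_learning_loop(
            initial,
            pool,
            lambda p: truths[p.patch_id],
            rounds=rounds,
            batch=batch,
            config1=LEARNER1_CONFIG,
            config2=LEARNER2_CONFIG,
            seed=run_seed,
        )
        iou_after = heldout_mean_iou(l1, heldout, truths)
        rows.append({"seed": s, "iou_before": iou_before, "iou_after": iou_after,
                     "improved": iou_after >= iou_before})
    return pd.DataFrame(rows, columns=["seed", "iou_before", "iou_after", "improved"])


def welch_type1_experiment(
    n_reps: int = 5000,
    n1: int = 3,
    n2: int = 6,
    sd1: float = 1.0,
    sd2: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the Welch test under a null simulation.

    Equal means, unequal variances, unbalanced groups; returns the
    rejection rate at the given alpha.
    """
    from .recovery import welch_t

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(0.0, sd1, n1)
        b = rng.normal(0.0, sd2, n2)
        res = welch_t(a.mean(), a.std(ddof=1), n1, b.mean(), b.std(ddof=1), n2)
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_reps
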