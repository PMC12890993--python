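"""Valid-area classification: artifact thresholding + pixel classifier.

The analyzable ("valid fluid") area of a slide is what remains after
excluding air bubbles and edge disturbances; it is the denominator of all
particle densities.  Detection runs in two stages, mirroring common
whole-slide practice: (1) intensity thresholding finds bright bubble
bodies (grown to cover their dark rims) and dark border disturbances;
(2) a two-class random-forest pixel classifier over intensity, texture and
morphological features assigns every remaining pixel to valid fluid or
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, morphology
from sklearn.ensemble import RandomForestClassifier

from .synthetic import SlideImage


class RegionLabel(IntEnum):
    VALID_FLUID = 0
    AIR_BUBBLE = 1
    EDGE_ARTIFACT = 2
    OTHER_ARTIFACT = 3
    UNCLASSIFIED = 4

    @property
    def is_artifact(self) -> bool:
        return self in (RegionLabel.AIR_BUBBLE, RegionLabel.EDGE_ARTIFACT, RegionLabel.OTHER_ARTIFACT)


@dataclass
class RegionMask:
    """Per-pixel region labels plus physical calibration."""

    labels: np.ndarray  # uint8 of RegionLabel values
    mpp: float

    def __post_init__(self) -> None:
        if not self.mpp > 0:
            raise ValueError("microns-per-pixel must be > 0")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels == RegionLabel.VALID_FLUID

    @property
    def valid_area_mm2(self) -> float:
        return int(self.valid_mask.sum()) * (self.mpp / 1000.0) ** 2

    def area_mm2(self, label: RegionLabel) -> float:
        return int((self.labels == label).sum()) * (self.mpp / 1000.0) ** 2

    def summary(self) -> dict:
        return {lab.name.lower(): self.area_mm2(lab) for lab in RegionLabel}


def region_mask_from_truth(truth) -> RegionMask:
    """Oracle region mask from generator ground truth."""
    labels = np.full(truth.artifact_labels.shape, RegionLabel.VALID_FLUID, dtype=np.uint8)
    labels[truth.artifact_labels == 1] = RegionLabel.AIR_BUBBLE
    labels[truth.artifact_labels == 2] = RegionLabel.EDGE_ARTIFACT
    return RegionMask(labels, truth.mpp)


def threshold_artifacts(
    image: SlideImage,
    bright_cutoff: float = 225.0,
    dark_cutoff: float = 90.0,
    border_band_px: int = 24,
    min_area_px: int = 100,
    rim_pad_px: int = 3,
) -> RegionMask:
    """Preliminary artifact mask from intensity thresholds.

    Pixels at or above ``bright_cutoff`` seed air-bubble candidates (small
    components removed, holes filled, then grown by ``rim_pad_px`` to
    include the dark rim).  The border band of ``border_band_px`` is
    excluded as edge disturbance, together with any dark
    (<= ``dark_cutoff``) structure connected to it.  Ties at a cutoff are
    assigned to the artifact class (conservative exclusion).  Everything
    else is left unclassified for the pixel classifier.
    """
    if dark_cutoff >= bright_cutoff:
        raise ValueError("dark_cutoff must be below bright_cutoff")
    if border_band_px < 0:
        raise ValueError("border band must be >= 0")
    px = image.pixels.astype(float)
    labels = np.full(px.shape, RegionLabel.UNCLASSIFIED, dtype=np.uint8)
    h, w = px.shape

    # edge disturbances: the border band, plus dark structures touching it
    if border_band_px > 0:
        band = np.zeros((h, w), dtype=bool)
        b = min(border_band_px, h), min(border_band_px, w)
        band[: b[0], :] = True
        band[h - b[0] :, :] = True
        band[:, : b[1]] = True
        band[:, w - b[1] :] = True
        dark = px <= dark_cutoff
        lab, _ = ndimage.label(dark, structure=np.ones((3, 3)))
        touching = np.unique(lab[band & dark])
        touching = touching[touching > 0]
        edge = band.copy()
        if touching.size:
            edge |= np.isin(lab, touching)
        labels[edge] = RegionLabel.EDGE_ARTIFACT

    # air bubbles: bright bodies grown over their rims
    bright = px >= bright_cutoff
    if min_area_px > 0:
        bright = morphology.remove_small_objects(bright, max_size=min_area_px - 1)
    bright = ndimage.binary_fill_holes(bright)
    if rim_pad_px > 0:
        bright = ndimage.binary_dilation(bright, structure=morphology.disk(rim_pad_px))
    labels[bright] = RegionLabel.AIR_BUBBLE

    return RegionMask(labels, image.mpp)


def extract_pixel_features(image: SlideImage, scales: Sequence[float] = (1.0, 4.0)) -> np.ndarray:
    """Per-pixel feature stack: intensity, texture, morphology.

    Returns an H x W x F float32 array with
    F = 1 (raw) + 2*len(scales) (smoothed intensity and local SD per scale)
    + 2 (gradient magnitude, 3x3 local variance)
    + 2 (white/black top-hat residuals).
    """
    if len(scales) < 1:
        raise ValueError("at least one smoothing scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("smoothing scales must be > 0")
    px = image.pixels.astype(np.float32)
    feats = [px]
    for s in scales:
        sm = ndimage.gaussian_filter(px, s)
        sq = ndimage.gaussian_filter(px**2, s)
        feats.append(sm)
        feats.append(np.sqrt(np.maximum(sq - sm**2, 0.0)))
    feats.append(filters.sobel(px).astype(np.float32))
    mean3 = ndimage.uniform_filter(px, 3)
    feats.append(np.maximum(ndimage.uniform_filter(px**2, 3) - mean3**2, 0.0))
    selem = morphology.disk(3)
    feats.append(morphology.white_tophat(px, selem))
    feats.append(morphology.black_tophat(px, selem))
    return np.stack(feats, axis=-1).astype(np.float32)


@dataclass
class RegionClassifier:
    """Two-class (valid fluid vs artifact) tree-ensemble pixel classifier."""

    model: RandomForestClassifier
    n_features: int
    seed: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict class per pixel (1 = valid fluid, 2 = artifact)."""
        flat = features.reshape(-1, features.shape[-1])
        if flat.shape[1] != self.n_features:
            raise ValueError("feature count does not match the trained classifier")
        return self.model.predict(flat).reshape(features.shape[:-1])


def train_region_classifier(
    features: np.ndarray,
    annotations: np.ndarray,
    seed: int = 0,
    n_estimators: int = 100,
    max_train_pixels: int = 50_000,
) -> RegionClassifier:
    """Train the two-class pixel classifier from annotated pixels.

    ``annotations`` is an H x W array with 0 = unlabeled, 1 = valid fluid,
    2 = artifact; both classes must be present.  Training pixels are
    subsampled deterministically to ``max_train_pixels``.
    """
    if features.shape[:2] != annotations.shape:
        raise ValueError("features and annotations must share the raster shape")
    ys, xs = np.nonzero(annotations)
    y = annotations[ys, xs]
    present = np.unique(y)
    if not {1, 2}.issubset(present):
        raise ValueError(
            "annotations must contain both classes (valid fluid and artifact); "
            f"found classes {sorted(int(c) for c in present)}"
        )
    rng = np.random.default_rng(seed)
    if ys.size > max_train_pixels:
        keep = rng.choice(ys.size, size=max_train_pixels, replace=False)
        keep.sort()
        ys, xs, y = ys[keep], xs[keep], y[keep]
    X = features[ys, xs]
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(X, y)
    return RegionClassifier(model, features.shape[-1], seed)


def classify_valid_area(
    image: SlideImage,
    clf: RegionClassifier,
    preliminary: RegionMask,
    features: Optional[np.ndarray] = None,
) -> RegionMask:
    """Resolve unclassified pixels into valid fluid or artifact.

    Pixels already labeled by thresholding keep their label; the
    classifier assigns the rest, yielding a full partition of the raster.
    """
    if preliminary.labels.shape != image.pixels.shape:
        raise ValueError("preliminary mask raster does not match the image")
    labels = preliminary.labels.copy()
    todo = labels == RegionLabel.UNCLASSIFIED
    if todo.any():
        if features is None:
            features = extract_pixel_features(image)
        flat = features[todo]
        if flat.shape[1] != clf.n_features:
            raise ValueError("feature count does not match the trained classifier")
        pred = clf.model.predict(flat)
        out = np.where(pred == 1, RegionLabel.VALID_FLUID, RegionLabel.OTHER_ARTIFACT)
        labels[todo] = out.astype(np.uint8)
    return RegionMask(labels, image.mpp)
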