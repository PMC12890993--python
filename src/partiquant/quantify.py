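"""Particle detections, Feret sizing, size bins and densities.

A binary segmentation mask is decomposed into 8-connected components
("detections"), each sized by its maximum caliper (Feret) length, assigned
to one of four size bins (<100, 100-250, 250-500, >500 um), filtered to
the valid fluid area, and summarised as particles per mm^2 of valid area
per bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .regions import RegionLabel, RegionMask

#: half-open size-bin edges in micrometres and their labels
BIN_EDGES_UM: Tuple[float, ...] = (100.0, 250.0, 500.0)
BIN_LABELS: Tuple[str, ...] = ("<100", "100-250", "250-500", ">500")


def classify_size_bin(size_um: float, edges: Sequence[float] = BIN_EDGES_UM) -> str:
    """Assign a particle size to its bin.

    Bins are half-open with the lower edge inclusive: [0,100), [100,250),
    [250,500), [500,inf) -- so exactly 100.0 falls in "100-250" and exactly
    500.0 in ">500".
    """
    if not size_um > 0:
        raise ValueError(f"particle size must be > 0, got {size_um}")
    idx = int(np.searchsorted(np.asarray(edges, dtype=float), size_um, side="right"))
    return BIN_LABELS[idx]


def _boundary_pixels(coords: np.ndarray) -> np.ndarray:
    """Pixels of a footprint with at least one 4-neighbour outside it."""
    r0, c0 = coords.min(axis=0)
    crop = np.zeros((coords[:, 0].max() - r0 + 3, coords[:, 1].max() - c0 + 3), dtype=bool)
    crop[coords[:, 0] - r0 + 1, coords[:, 1] - c0 + 1] = True
    interior = crop & np.roll(crop, 1, 0) & np.roll(crop, -1, 0) & np.roll(crop, 1, 1) & np.roll(crop, -1, 1)
    br, bc = np.nonzero(crop & ~interior)
    return np.stack([br + r0 - 1, bc + c0 - 1], axis=1)


def measure_size(footprint: np.ndarray, mpp: float) -> float:
    """Maximum caliper (Feret) length of a footprint in micrometres.

    Computed as the maximum pairwise distance between boundary pixel
    centres plus one pixel pitch (so a single pixel measures one pixel
    pitch), scaled by microns-per-pixel.  ``footprint`` is an N x 2 array
    of (row, col) pixel coordinates.
    """
    if not mpp > 0:
        raise ValueError("microns-per-pixel must be > 0")
    coords = np.asarray(footprint)
    if coords.size == 0:
        raise ValueError("footprint must contain at least one pixel")
    if coords.shape[0] == 1:
        return float(mpp)
    pts = _boundary_pixels(coords).astype(float)
    if pts.shape[0] > 60:
        # the diameter is attained on the convex hull; prune first
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) sets
            pass
    if pts.shape[0] == 1:
        return float(mpp)
    return float((pdist(pts).max() + 1.0) * mpp)


@dataclass
class ParticleDetection:
    """One connected particle footprint with physical measurements."""

    detection_id: int
    footprint: np.ndarray  # N x 2 (row, col) pixel coordinates
    centroid: Tuple[float, float]  # (row, col) in slide pixels
    size_um: float
    area_um2: float
    bin: str
    morphology: Optional[str] = None


def segment_to_detections(mask: np.ndarray, mpp: float) -> List[ParticleDetection]:
    """Convert a binary particle mask into detections.

    One detection per 8-connected component, ordered by scanline position
    of the centroid (row, then column).  An empty mask yields an empty
    list.
    """
    if not mpp > 0:
        raise ValueError("microns-per-pixel must be > 0")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    out: List[ParticleDetection] = []
    for i, p in enumerate(props, start=1):
        size = measure_size(p.coords, mpp)
        out.append(
            ParticleDetection(
                detection_id=i,
                footprint=p.coords,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                size_um=size,
                area_um2=float(p.area) * mpp**2,
                bin=classify_size_bin(size),
            )
        )
    return out


def filter_to_valid_area(
    detections: Sequence[ParticleDetection],
    region: RegionMask,
    min_overlap: float = 0.5,
    with_removed: bool = False,
):
    """Keep detections lying (mostly) in valid fluid.

    A detection is retained iff the fraction of its footprint inside the
    valid-fluid region is at least ``min_overlap``; detections inside
    bubbles or edge disturbances are dropped.  With ``with_removed=True``
    also returns a log of removals (detection_id, valid_fraction).
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    valid = region.valid_mask
    kept: List[ParticleDetection] = []
    removed: List[dict] = []
    for d in detections:
        fp = d.footprint
        if fp[:, 0].max() >= valid.shape[0] or fp[:, 1].max() >= valid.shape[1]:
            raise ValueError("detection coordinates fall outside the region mask raster")
        frac = float(valid[fp[:, 0], fp[:, 1]].mean())
        if frac >= min_overlap:
            kept.append(d)
        else:
            removed.append(
                {"detection_id": d.detection_id, "valid_fraction": frac, "reason": "outside_valid_area"}
            )
    if with_removed:
        return kept, pd.DataFrame(removed, columns=["detection_id", "valid_fraction", "reason"])
    return kept


def compute_density(
    detections: Sequence[ParticleDetection],
    region: RegionMask,
    condition: str,
) -> pd.DataFrame:
    """Per-bin particle densities over the valid fluid area.

    Returns one row per size bin (zero-count bins included) with columns
    condition, bin, count, valid_area_mm2, density_per_mm2.
    """
    area = region.valid_area_mm2
    if not area > 0:
        raise ValueError("valid area is zero; densities are undefined")
    counts = {b: 0 for b in BIN_LABELS}
    for d in detections:
        counts[d.bin] += 1
    rows = [
        {
            "condition": condition,
            "bin": b,
            "count": counts[b],
            "valid_area_mm2": area,
            "density_per_mm2": counts[b] / area,
        }
        for b in BIN_LABELS
    ]
    return pd.DataFrame(rows, columns=["condition", "bin", "count", "valid_area_mm2", "density_per_mm2"])


def detections_to_frame(detections: Sequence[ParticleDetection]) -> pd.DataFrame:
    """One row per detection: id, centroid, size, area, bin."""
    return pd.DataFrame(
        [
            {
                "detection_id": d.detection_id,
                "centroid_row": d.centroid[0],
                "centroid_col": d.centroid[1],
                "size_um": d.size_um,
                "area_um2": d.area_um2,
                "bin": d.bin,
            }
            for d in detections
        ],
        columns=["detection_id", "centroid_row", "centroid_col", "size_um", "area_um2", "bin"],
    )
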