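"""File formats: slides (TIFF/PNG + sidecar), label masks, GeoJSON, CSV.

Slides are written as TIFF with microns-per-pixel in the resolution tags
(pixels per centimetre), or as PNG with a JSON sidecar carrying the
calibration.  Detections and ground-truth particles are exchanged as
GeoJSON feature collections (one polygon per particle with ``size_um`` and
``bin``/``morphology`` properties), which round-trip with the
quantification module via rasterisation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Polygon, mapping, shape
from skimage import measure as skmeasure
from skimage.draw import polygon as draw_polygon

from .quantify import ParticleDetection
from .synthetic import GroundTruth, SlideImage


def write_slide(path: str | Path, slide: SlideImage) -> Path:
    """Write a slide as TIFF (mpp in resolution tags) or PNG + sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 10_000.0 / slide.mpp
        tifffile.imwrite(
            path,
            slide.pixels,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    elif path.suffix.lower() == ".png":
        Image.fromarray(slide.pixels).save(path)
        path.with_suffix(".json").write_text(json.dumps({"mpp": slide.mpp}))
    else:
        raise ValueError(f"unsupported slide format: {path.suffix}")
    return path


def read_slide(path: str | Path, mpp: Optional[float] = None) -> SlideImage:
    """Read a slide, recovering microns-per-pixel from metadata."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixels = page.asarray()
            if mpp is None:
                xres = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if xres is not None and unit is not None and unit.value == 3:
                    num, den = xres.value
                    mpp = 10_000.0 / (num / den)
        if mpp is None:
            raise ValueError("TIFF carries no resolution metadata; pass mpp explicitly")
    elif path.suffix.lower() == ".png":
        pixels = np.asarray(Image.open(path).convert("L"))
        if mpp is None:
            sidecar = path.with_suffix(".json")
            if not sidecar.exists():
                raise ValueError("PNG has no sidecar JSON; pass mpp explicitly")
            mpp = float(json.loads(sidecar.read_text())["mpp"])
    else:
        raise ValueError(f"unsupported slide format: {path.suffix}")
    return SlideImage(pixels, float(mpp))


def write_label_mask(path: str | Path, labels: np.ndarray) -> Path:
    """Write an integer label raster as a 8/16-bit TIFF."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.max() < 256:
        labels = labels.astype(np.uint8)
    elif labels.max() < 65536:
        labels = labels.astype(np.uint16)
    else:
        labels = labels.astype(np.uint32)
    tifffile.imwrite(path, labels)
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def _footprint_polygon(coords: np.ndarray) -> Polygon:
    """Polygon outline (in x=col, y=row pixel coordinates) of a footprint."""
    r0, c0 = coords.min(axis=0)
    crop = np.zeros((coords[:, 0].max() - r0 + 3, coords[:, 1].max() - c0 + 3), dtype=float)
    crop[coords[:, 0] - r0 + 1, coords[:, 1] - c0 + 1] = 1.0
    contours = skmeasure.find_contours(crop, 0.5)
    ring = max(contours, key=len)
    # contour is (row, col); GeoJSON wants (x, y) = (col, row)
    xy = [(float(c + c0 - 1), float(r + r0 - 1)) for r, c in ring]
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def detections_to_geojson(detections: Sequence[ParticleDetection]) -> dict:
    """Export detections as a GeoJSON FeatureCollection (pixel coordinates)."""
    features = []
    for d in detections:
        poly = _footprint_polygon(d.footprint)
        props = {"detection_id": d.detection_id, "size_um": d.size_um, "bin": d.bin}
        if d.morphology is not None:
            props["morphology"] = d.morphology
        features.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    return {"type": "FeatureCollection", "features": features}


def ground_truth_to_geojson(truth: GroundTruth) -> dict:
    """Export ground-truth particles as GeoJSON with morphology and size."""
    features = []
    for row in truth.particle_table.itertuples(index=False):
        coords = np.stack(np.nonzero(truth.particle_labels == row.particle_id), axis=1)
        poly = _footprint_polygon(coords)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {
                    "particle_id": int(row.particle_id),
                    "morphology": row.morphology,
                    "size_um": float(row.size_um),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_mask(collection: dict, shape_hw: tuple) -> np.ndarray:
    """Rasterise a GeoJSON FeatureCollection back into a binary mask."""
    mask = np.zeros(shape_hw, dtype=bool)
    for feat in collection.get("features", []):
        geom = shape(feat["geometry"])
        polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
        for poly in polys:
            xs, ys = poly.exterior.xy
            rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape=shape_hw)
            mask[rr, cc] = True
    return mask


def write_geojson(path: str | Path, collection: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(collection))
    return path


def read_geojson(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_measurements_csv(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"method", "replicate", "extracted_mg", "remaining_mg"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"measurement CSV lacks columns: {sorted(missing)}")
    return frame
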