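"""Seeded synthetic brightfield slides with exact ground truth.

The generator emulates the statistical structure of cotton-filtered
tablet-extract slides: a pale fluid background with a slow illumination
gradient and sensor noise, bright air bubbles with dark rims, dark edge
disturbances along the slide border, and three particle morphologies --
small dark circular coating fragments ("black dots"), elongated
crystal-like fragments, and irregular "cotton-like" blobs.  Particle
counts are Poisson in the analyzable (artifact-free) area and sizes are
log-normal per morphology, so every downstream stage can be validated
against known rates.

It also simulates replicate morphine mass measurements (filtrate +
cotton-ball wash) as independent normals truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line, polygon as draw_polygon

from .conditions import ConditionSpec, MethodRecoveryParams, MORPHOLOGIES

# rendered intensity model (uint8): pale fluid, dark particles/edges,
# bright bubble interiors with dark rims
BACKGROUND_MEAN = 200.0
BACKGROUND_NOISE_SD = 3.0
ILLUMINATION_AMPLITUDE = 8.0
PARTICLE_INTENSITY = {"black_dot": 25.0, "crystal": 100.0, "cotton": 120.0}
BUBBLE_INTERIOR = 238.0
BUBBLE_RIM = 70.0
EDGE_INTENSITY = 45.0
#: minimum contrast (grey levels) between a particle pixel and the local fluid
CONTRAST_MARGIN = 40.0


@dataclass
class SlideImage:
    """A scanned slide raster with its physical calibration."""

    pixels: np.ndarray  # 2-D uint8 grayscale
    mpp: float  # microns per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("slide raster must be 2-D with positive dimensions")
        if not self.mpp > 0:
            raise ValueError(f"microns-per-pixel must be > 0, got {self.mpp}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def area_mm2(self) -> float:
        return self.pixels.size * (self.mpp / 1000.0) ** 2


@dataclass
class GroundTruth:
    """Exact per-pixel truth accompanying a synthetic slide.

    ``particle_labels`` holds one positive integer id per particle
    (0 = no particle); ``artifact_labels`` uses 0 = fluid, 1 = air bubble,
    2 = edge disturbance.  ``particle_table`` has one row per rendered
    particle: particle_id, morphology, size_um, centroid_row, centroid_col.
    """

    particle_labels: np.ndarray  # uint16/uint32 label raster
    artifact_labels: np.ndarray  # uint8 {0,1,2}
    particle_table: pd.DataFrame
    mpp: float

    @property
    def particle_mask(self) -> np.ndarray:
        return self.particle_labels > 0

    @property
    def valid_mask(self) -> np.ndarray:
        """Analyzable fluid area (particles count as fluid)."""
        return self.artifact_labels == 0

    @property
    def valid_area_mm2(self) -> float:
        return int(self.valid_mask.sum()) * (self.mpp / 1000.0) ** 2


def _smooth_circular_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Circularly smoothed Gaussian noise, used for ragged blob outlines."""
    raw = rng.normal(0.0, 1.0, n)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    smooth = np.convolve(np.concatenate([raw[-2:], raw, raw[:2]]), kernel, mode="valid")
    s = smooth.std()
    if s > 0:
        smooth *= sd / s
    return smooth


def render_particle(
    morphology: str,
    size_um: float,
    mpp: float,
    seed: Optional[int | np.random.Generator] = None,
) -> np.ndarray:
    """Render one particle footprint as a boolean raster.

    The footprint's maximum caliper length (max boundary pixel-centre
    distance plus one pixel pitch) matches ``size_um`` to within one pixel.
    ``black_dot`` renders a filled disc, ``crystal`` an elongated rotated
    ellipse (aspect ratio >= 3), ``cotton`` an irregular star-shaped blob
    with a ragged border.
    """
    if morphology not in MORPHOLOGIES:
        raise ValueError(f"unknown morphology {morphology!r}; expected one of {MORPHOLOGIES}")
    if not size_um > 0:
        raise ValueError(f"particle size must be > 0, got {size_um}")
    if not mpp > 0:
        raise ValueError(f"microns-per-pixel must be > 0, got {mpp}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    d = max(1, round(size_um / mpp))  # target caliper in pixels
    if d == 1:
        return np.ones((1, 1), dtype=bool)

    span = (d - 1) / 2.0  # max distance of a pixel centre from the centre

    if morphology == "black_dot":
        c = np.arange(d) - (d - 1) / 2.0
        yy, xx = np.meshgrid(c, c, indexing="ij")
        fp = yy**2 + xx**2 <= (span + 0.25) ** 2
    elif morphology == "crystal":
        aspect = rng.uniform(3.0, 5.0)
        theta = rng.uniform(0.0, np.pi)
        a = span + 0.25
        b = max(0.6, a / aspect)
        n = d + 2
        c = np.arange(n) - (n - 1) / 2.0
        yy, xx = np.meshgrid(c, c, indexing="ij")
        u = xx * np.cos(theta) + yy * np.sin(theta)
        v = -xx * np.sin(theta) + yy * np.cos(theta)
        fp = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # draw the major axis explicitly, snapping its endpoints to the
        # integer pair whose span best matches the target caliper (the
        # ellipse tips alone can quantise away at oblique angles)
        c0 = (n - 1) / 2.0
        ey, ex = span * np.sin(theta), span * np.cos(theta)
        best, best_err = None, np.inf
        for fy1 in (np.floor, np.ceil):
            for fx1 in (np.floor, np.ceil):
                for fy2 in (np.floor, np.ceil):
                    for fx2 in (np.floor, np.ceil):
                        p1 = (int(fy1(c0 - ey)), int(fx1(c0 - ex)))
                        p2 = (int(fy2(c0 + ey)), int(fx2(c0 + ex)))
                        err = abs(np.hypot(p2[0] - p1[0], p2[1] - p1[1]) - (d - 1))
                        if err < best_err:
                            best, best_err = (p1, p2), err
        (y1, x1), (y2, x2) = best
        lr, lc = draw_line(y1, x1, y2, x2)
        keep = (lr >= 0) & (lr < n) & (lc >= 0) & (lc < n)
        fp[lr[keep], lc[keep]] = True
    else:  # cotton
        nv = 24
        phi = np.linspace(0.0, 2 * np.pi, nv, endpoint=False)
        radii = np.clip(1.0 + _smooth_circular_noise(rng, nv, 0.3), 0.35, None)
        vx = radii * np.cos(phi)
        vy = radii * np.sin(phi)
        pts = np.stack([vy, vx], axis=1)
        dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        i, j = np.unravel_index(int(np.argmax(dists)), dists.shape)
        # rotate the extremal vertex pair onto the x-axis so coordinate
        # rounding perturbs the caliper by less than a pixel
        ang = np.arctan2(vy[j] - vy[i], vx[j] - vx[i])
        ca, sa = np.cos(-ang), np.sin(-ang)
        vx, vy = vx * ca - vy * sa, vx * sa + vy * ca
        scale = (d - 1) / dists.max()
        vy *= scale
        vx *= scale
        # canvas sized from the actual vertex extent so nothing clips
        vy = vy - vy.min() + 2.0
        vx = vx - vx.min() + 2.0
        ny = int(np.ceil(vy.max())) + 3
        nx = int(np.ceil(vx.max())) + 3
        rr, cc = draw_polygon(vy, vx, shape=(ny, nx))
        fp = np.zeros((ny, nx), dtype=bool)
        fp[rr, cc] = True
        # trace the outline ring so every (possibly spiky) vertex stays
        # 8-connected to the body and the caliper survives rasterisation
        iy = np.round(vy).astype(int)
        ix = np.round(vx).astype(int)
        for k in range(nv):
            lr, lc = draw_line(iy[k], ix[k], iy[(k + 1) % nv], ix[(k + 1) % nv])
            fp[lr, lc] = True

    # keep the largest 8-connected component and crop to the tight bbox
    lab, nlab = ndimage.label(fp, structure=np.ones((3, 3)))
    if nlab > 1:
        sizes = ndimage.sum_labels(fp, lab, index=np.arange(1, nlab + 1))
        fp = lab == (1 + int(np.argmax(sizes)))
    rows = np.any(fp, axis=1)
    cols = np.any(fp, axis=0)
    return fp[np.ix_(rows, cols)]


def _illumination_field(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    """Slow linear illumination gradient with random orientation."""
    h, w = shape
    gy = rng.uniform(-1.0, 1.0)
    gx = rng.uniform(-1.0, 1.0)
    yy = np.linspace(-0.5, 0.5, h)[:, None]
    xx = np.linspace(-0.5, 0.5, w)[None, :]
    return ILLUMINATION_AMPLITUDE * (gy * yy + gx * xx)


def _stamp_bubbles(
    rng: np.random.Generator,
    pixels: np.ndarray,
    artifact: np.ndarray,
    density_per_mm2: float,
    mpp: float,
) -> None:
    h, w = pixels.shape
    area_mm2 = h * w * (mpp / 1000.0) ** 2
    n = rng.poisson(density_per_mm2 * area_mm2)
    for _ in range(n):
        radius_um = rng.lognormal(np.log(120.0), np.log(1.5))
        r = max(4, round(radius_um / mpp))
        cy = rng.integers(0, h)
        cx = rng.integers(0, w)
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        yy, xx = np.meshgrid(np.arange(y0, y1) - cy, np.arange(x0, x1) - cx, indexing="ij")
        dist2 = yy**2 + xx**2
        disc = dist2 <= r**2
        rim = disc & (dist2 >= (r - max(2, r // 10)) ** 2)
        pixels[y0:y1, x0:x1][disc] = BUBBLE_INTERIOR
        pixels[y0:y1, x0:x1][rim] = BUBBLE_RIM
        artifact[y0:y1, x0:x1][disc] = 1


def _stamp_edges(rng: np.random.Generator, pixels: np.ndarray, artifact: np.ndarray) -> None:
    h, w = pixels.shape
    for side in range(4):
        width = int(rng.integers(6, 21))
        if side == 0:
            sl = (slice(0, width), slice(None))
        elif side == 1:
            sl = (slice(h - width, h), slice(None))
        elif side == 2:
            sl = (slice(None), slice(0, width))
        else:
            sl = (slice(None), slice(w - width, w))
        pixels[sl] = EDGE_INTENSITY + rng.normal(0.0, 5.0, pixels[sl].shape)
        artifact[sl] = 2


def generate_slide(
    spec: ConditionSpec,
    mpp: float = 1.0,
    size_px: Tuple[int, int] = (4096, 4096),
    seed: int = 0,
) -> Tuple[SlideImage, GroundTruth]:
    """Generate a seeded slide with byte-exact ground truth.

    Particle counts per morphology are Poisson with mean density x
    analyzable area; sizes are log-normal per the condition spec; particles
    are placed uniformly over the artifact-free area, rejection-sampled so
    footprints never touch artifacts or each other (separation keeps
    ground-truth counts identifiable by connected components).
    """
    if not mpp > 0:
        raise ValueError(f"microns-per-pixel must be > 0, got {mpp}")
    h, w = int(size_px[0]), int(size_px[1])
    if h < 32 or w < 32:
        raise ValueError(f"slide must be at least 32x32 px, got {size_px}")
    rng = np.random.default_rng(seed)

    pixels = BACKGROUND_MEAN + _illumination_field(rng, (h, w)) + rng.normal(
        0.0, BACKGROUND_NOISE_SD, (h, w)
    )
    artifact = np.zeros((h, w), dtype=np.uint8)

    if spec.edge_artifact:
        _stamp_edges(rng, pixels, artifact)
    _stamp_bubbles(rng, pixels, artifact, spec.bubble_density_per_mm2, mpp)

    valid = artifact == 0
    valid_area_mm2 = int(valid.sum()) * (mpp / 1000.0) ** 2

    # draw all particles first (counts + sizes), then place large-to-small
    draws: List[Tuple[str, float]] = []
    for name in MORPHOLOGIES:  # fixed iteration order for determinism
        if name not in spec.morphologies:
            continue
        m = spec.morphologies[name]
        count = rng.poisson(m.density_per_mm2 * valid_area_mm2)
        sizes = np.exp(rng.normal(np.log(m.median_um), np.log(m.gsd), count))
        draws.extend((name, float(s)) for s in sizes)
    draws.sort(key=lambda t: -t[1])

    particle_labels = np.zeros((h, w), dtype=np.uint32)
    blocked = ~valid  # artifact pixels + 1-px dilated particle footprints
    rows: List[dict] = []
    valid_coords = np.flatnonzero(valid)
    next_id = 1
    struct = np.ones((3, 3), dtype=bool)
    for name, size_um in draws:
        fp = render_particle(name, size_um, mpp, rng)
        fh, fw = fp.shape
        # dilate on a padded canvas so the 1-px separation margin survives
        # at the bbox border (prevents adjacent footprints from merging)
        fp_dil = ndimage.binary_dilation(np.pad(fp, 1), structure=struct)
        placed = False
        for _ in range(200):
            flat = valid_coords[rng.integers(0, valid_coords.size)]
            cy, cx = divmod(int(flat), w)
            y0 = cy - fh // 2
            x0 = cx - fw // 2
            if y0 < 1 or x0 < 1 or y0 + fh > h - 1 or x0 + fw > w - 1:
                continue
            if blocked[y0 - 1 : y0 + fh + 1, x0 - 1 : x0 + fw + 1][fp_dil].any():
                continue
            target = pixels[y0 : y0 + fh, x0 : x0 + fw]
            base = PARTICLE_INTENSITY[name]
            target[fp] = base + rng.normal(0.0, 6.0, int(fp.sum()))
            particle_labels[y0 : y0 + fh, x0 : x0 + fw][fp] = next_id
            blocked[y0 - 1 : y0 + fh + 1, x0 - 1 : x0 + fw + 1] |= fp_dil
            ys, xs = np.nonzero(fp)
            rows.append(
                {
                    "particle_id": next_id,
                    "morphology": name,
                    "size_um": size_um,
                    "centroid_row": y0 + float(ys.mean()),
                    "centroid_col": x0 + float(xs.mean()),
                }
            )
            next_id += 1
            placed = True
            break
        # a particle that cannot be placed after 200 tries is dropped; at
        # default occupancies this is vanishingly rare
        del placed

    table = pd.DataFrame(
        rows, columns=["particle_id", "morphology", "size_um", "centroid_row", "centroid_col"]
    )
    image = SlideImage(np.clip(pixels, 0, 255).astype(np.uint8), mpp)
    truth = GroundTruth(particle_labels, artifact, table, mpp)
    return image, truth


@dataclass(frozen=True)
class ExtractionMeasurement:
    """One replicate morphine measurement for one protocol."""

    method: str
    replicate: int
    extracted_mg: float
    remaining_mg: float

    def __post_init__(self) -> None:
        if self.extracted_mg < 0 or self.remaining_mg < 0:
            raise ValueError("masses must be >= 0")


def generate_measurements(
    method_params: Dict[str, MethodRecoveryParams],
    n: Optional[Dict[str, int]] = None,
    seed: int = 0,
) -> List[ExtractionMeasurement]:
    """Simulate replicate morphine masses for each protocol.

    Draws are independent normals at the configured means/SDs, truncated at
    zero (masses cannot be negative); truncation is negligible at the
    default parameters.  Deterministic for a fixed seed.
    """
    if not method_params:
        raise ValueError("method_params must name at least one method")
    rng = np.random.default_rng(seed)
    out: List[ExtractionMeasurement] = []
    for method in sorted(method_params):
        p = method_params[method]
        reps = (n or {}).get(method, p.n)
        if reps < 1:
            raise ValueError(f"replicate count for {method} must be >= 1")
        extracted = np.maximum(0.0, rng.normal(p.extracted_mean_mg, p.extracted_sd_mg, reps))
        remaining = np.maximum(0.0, rng.normal(p.remaining_mean_mg, p.remaining_sd_mg, reps))
        out.extend(
            ExtractionMeasurement(method, i + 1, float(e), float(r))
            for i, (e, r) in enumerate(zip(extracted, remaining))
        )
    return out


def measurements_to_frame(measurements: List[ExtractionMeasurement]) -> pd.DataFrame:
    """Tabulate measurements as method,replicate,extracted_mg,remaining_mg."""
    return pd.DataFrame(
        [
            {
                "method": m.method,
                "replicate": m.replicate,
                "extracted_mg": m.extracted_mg,
                "remaining_mg": m.remaining_mg,
            }
            for m in measurements
        ],
        columns=["method", "replicate", "extracted_mg", "remaining_mg"],
    )


def ground_truth_region_labels(truth: GroundTruth) -> np.ndarray:
    """Two-class pixel labels for region-classifier training.

    1 = valid fluid (particles count as fluid), 2 = artifact.
    """
    return np.where(truth.artifact_labels > 0, 2, 1).astype(np.uint8)
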