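"""Shared fixtures: small synthetic slides and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from partiquant.conditions import DEFAULT_CONDITIONS
from partiquant.synthetic import generate_slide


@pytest.fixture(scope="session")
def slide_a():
    """Condition-A slide, 600x600 px at 2 um/px (~1.4 mm^2)."""
    return generate_slide(DEFAULT_CONDITIONS["A"], mpp=2.0, size_px=(600, 600), seed=7)


@pytest.fixture(scope="session")
def slide_blank():
    return generate_slide(DEFAULT_CONDITIONS["blank"], mpp=2.0, size_px=(600, 600), seed=7)


@pytest.fixture(scope="session")
def slide_b():
    """Condition-B slide (large particles), 800x800 px at 2 um/px."""
    return generate_slide(DEFAULT_CONDITIONS["B"], mpp=2.0, size_px=(800, 800), seed=11)


# ---- independent oracles (deliberately naive implementations) ----


def brute_force_feret_px(footprint_coords: np.ndarray) -> float:
    """All-pairs max distance between boundary pixel centres, +1.

    Boundary = pixels with a 4-neighbour outside the footprint, found by a
    naive set lookup (no morphology, no convex hull).
    """
    pts = np.asarray(footprint_coords, dtype=int)
    if len(pts) == 1:
        return 1.0
    cells = {(int(r), int(c)) for r, c in pts}
    boundary = [
        (r, c)
        for r, c in cells
        if not all(q in cells for q in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)))
    ]
    b = np.asarray(boundary, dtype=float)
    d2 = ((b[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()) + 1.0)


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 8-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
    return count


def pixel_count_iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU by explicit pixel loops (tiny masks only)."""
    inter = union = 0
    for x, y in zip(np.asarray(a, dtype=bool).ravel(), np.asarray(b, dtype=bool).ravel()):
        if x and y:
            inter += 1
        if x or y:
            union += 1
    return 1.0 if union == 0 else inter / union
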