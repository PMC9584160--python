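"""Elemental correlation analysis of paired XRF maps.

Co-located elements betray chemical phases: plotting per-pixel intensities
of two element maps against each other turns each stoichiometric
relationship into a linear branch in the scatter.  This module builds the
paired point cloud, selects branches with deterministic geometric regions
(box, polygon, or a band around a line — a reproducible stand-in for an
interactive lasso), and back-projects selections to binary pixel masks on
the map coordinates for downstream spectrum extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, ElementMap

__all__ = [
    "PairedPoints",
    "scatter_pairs",
    "select_region",
    "backproject",
    "pearson_r",
]


@dataclass
class PairedPoints:
    """Per-pixel (A, B) intensity pairs with their pixel origins."""

    element_a: str
    element_b: str
    a: np.ndarray  # (n,)
    b: np.ndarray  # (n,)
    origins: np.ndarray  # (n, 2) of (row, col), row-major order
    source_mask: BinaryMask

    def __len__(self) -> int:
        return self.a.size


def _map_data(m: ElementMap | np.ndarray) -> np.ndarray:
    return m.data if isinstance(m, ElementMap) else np.asarray(m, dtype=float)


def scatter_pairs(
    map_a: ElementMap | np.ndarray,
    map_b: ElementMap | np.ndarray,
    base_mask: BinaryMask | None = None,
    background_threshold: float = 0.02,
) -> PairedPoints:
    """Paired intensities of two maps over a base mask, row-major order.

    Without an explicit mask, pixels where map A exceeds
    ``background_threshold`` of its maximum are used — everything outside
    the primary element's footprint is background for correlation purposes.
    """
    a = _map_data(map_a)
    b = _map_data(map_b)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    if base_mask is None:
        base_mask = BinaryMask(a > background_threshold * a.max(), label="foreground")
    if base_mask.shape != a.shape:
        raise ValueError(
            f"base mask shape {base_mask.shape} does not match maps {a.shape}"
        )
    if base_mask.n_selected == 0:
        raise ValueError("base mask selects no pixels")
    rows, cols = np.nonzero(base_mask.data)
    name_a = map_a.element if isinstance(map_a, ElementMap) else "A"
    name_b = map_b.element if isinstance(map_b, ElementMap) else "B"
    return PairedPoints(
        element_a=name_a,
        element_b=name_b,
        a=a[rows, cols],
        b=b[rows, cols],
        origins=np.column_stack([rows, cols]),
        source_mask=base_mask,
    )


def _points_in_polygon(x: np.ndarray, y: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd-rule point-in-polygon, boundary-inclusive."""
    n = len(vertices)
    inside = np.zeros(x.size, dtype=bool)
    on_edge = np.zeros(x.size, dtype=bool)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # boundary check: point on segment
        cross = (x - x1) * (y2 - y1) - (y - y1) * (x2 - x1)
        within = (
            (np.minimum(x1, x2) - 1e-12 <= x)
            & (x <= np.maximum(x1, x2) + 1e-12)
            & (np.minimum(y1, y2) - 1e-12 <= y)
            & (y <= np.maximum(y1, y2) + 1e-12)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
        # ray casting (horizontal ray to +x)
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < np.where(cond, x_int, np.inf))
    return inside | on_edge


def select_region(
    points: PairedPoints,
    polygon: np.ndarray | list[tuple[float, float]] | None = None,
    box: tuple[float, float, float, float] | None = None,
    band: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Indices of points inside a geometric region (boundary counts inside).

    Exactly one region type:
      * ``polygon`` — (x, y) vertices, even-odd rule;
      * ``box`` — (x_min, x_max, y_min, y_max) axis-aligned;
      * ``band`` — (slope, intercept, tolerance): |b - (slope*a + intercept)|
        <= tolerance, the reproducible analogue of shading a linear branch.
    """
    given = [g is not None for g in (polygon, box, band)]
    if sum(given) != 1:
        raise ValueError("specify exactly one of polygon, box, band")
    x, y = points.a, points.b
    if polygon is not None:
        verts = np.asarray(polygon, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        # shoelace area; zero-area polygons select nothing meaningful
        xs, ys = verts[:, 0], verts[:, 1]
        area = 0.5 * abs(
            np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))
        )
        if area == 0:
            raise ValueError("degenerate polygon with zero area")
        keep = _points_in_polygon(x, y, verts)
    elif box is not None:
        x_min, x_max, y_min, y_max = box
        keep = (x >= x_min) & (x <= x_max) & (y >= y_min) & (y <= y_max)
    else:
        slope, intercept, tol = band
        if tol <= 0:
            raise ValueError("band tolerance must be > 0")
        keep = np.abs(y - (slope * x + intercept)) <= tol
    return np.nonzero(keep)[0]


def backproject(
    points: PairedPoints,
    indices: np.ndarray,
    spatial_shape: tuple[int, int] | None = None,
    label: str = "selection",
) -> BinaryMask:
    """Binary mask true exactly at the selected points' pixel origins."""
    shape = spatial_shape or points.source_mask.shape
    indices = np.asarray(indices, dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= len(points)):
        raise IndexError("selection index out of range")
    mask = np.zeros(shape, dtype=bool)
    if indices.size:
        rows = points.origins[indices, 0]
        cols = points.origins[indices, 1]
        mask[rows, cols] = True
    return BinaryMask(mask, label=label)


def pearson_r(
    map_a: ElementMap | np.ndarray,
    map_b: ElementMap | np.ndarray,
    mask: BinaryMask | None = None,
) -> float:
    """Pearson correlation of two maps over unmasked pixels."""
    a = _map_data(map_a)
    b = _map_data(map_b)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError("mask shape does not match maps")
        a, b = a[mask.data], b[mask.data]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 3:
        raise ValueError("need at least 3 pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(a, b)[0, 1])
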