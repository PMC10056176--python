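"""Voronoi tessellation of object centroids and the Voronoi regularity index.

Given generators P = {p1, ..., pn}, the Euclidean Voronoi diagram assigns
each point q of the window to the cell of its nearest generator.  Cells here
are clipped exactly to the rectangular window by the mirror construction:
the generators are reflected across all four window edges before the
tessellation is computed, which makes every original cell a bounded convex
polygon whose union tiles the window.

The Voronoi regularity index (VRI) pools, over the included cells, the
distances from each cell's polygon centroid to its vertices; with D their
mean and S their standard deviation, VRI = D / S.  A large VRI indicates a
regular (lattice-like) arrangement; VRI near zero indicates irregularity.
For a perfect lattice all distances are equal (S = 0) and VRI is returned as
the +inf sentinel with a regular-pattern flag.  Cells touching the window
boundary are excluded by default because clipping distorts their distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from .shapestats import SegmentedObject

__all__ = [
    "VoronoiDiagram",
    "VriResult",
    "tessellate",
    "vri",
    "seeds_from_objects",
    "polygon_area",
    "polygon_centroid",
]


@dataclass
class VoronoiDiagram:
    seeds: np.ndarray  # (n, 2)
    cells: list[np.ndarray]  # per-seed (k, 2) CCW vertex arrays, clipped
    bounded_flags: np.ndarray  # True where the cell does not touch the window
    window: tuple[float, float, float, float]


@dataclass
class VriResult:
    distances: np.ndarray
    d_mean: float
    d_sd: float
    vri: float
    n_cells_used: int
    regular_pattern: bool = False
    per_cell_mean: bool = False
    notes: list = field(default_factory=list)


def polygon_area(verts: np.ndarray) -> float:
    """Shoelace area of a simple polygon."""
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(verts: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (shoelace moments)."""
    x, y = verts[:, 0], verts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-300:
        return verts.mean(axis=0)
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6.0 * a)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _order_ccw(verts: np.ndarray) -> np.ndarray:
    c = verts.mean(axis=0)
    ang = np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0])
    return verts[np.argsort(ang)]


def tessellate(points: np.ndarray,
               window: tuple[float, float, float, float] | None = None,
               ) -> VoronoiDiagram:
    """Euclidean Voronoi diagram of the points, clipped to the window.

    ``window`` is (xmin, xmax, ymin, ymax); defaults to the bounding box of
    the points.  Requires at least 3 non-collinear points.  Cells whose
    (clipped) polygon touches the window boundary are flagged unbounded.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (n, 2)")
    if np.linalg.matrix_rank(pts - pts[0]) < 2:
        raise ValueError("points are collinear: Voronoi diagram is degenerate")
    if window is None:
        window = (pts[:, 0].min(), pts[:, 0].max(),
                  pts[:, 1].min(), pts[:, 1].max())
    xmin, xmax, ymin, ymax = window
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("window must have positive extent")

    # mirror construction: reflect across each window edge so every original
    # cell comes out bounded and clipped exactly to the window
    left = pts * [-1, 1] + [2 * xmin, 0]
    right = pts * [-1, 1] + [2 * xmax, 0]
    down = pts * [1, -1] + [0, 2 * ymin]
    up = pts * [1, -1] + [0, 2 * ymax]
    vor = Voronoi(np.vstack([pts, left, right, down, up]))

    tol = 1e-9 * max(xmax - xmin, ymax - ymin)
    cells: list[np.ndarray] = []
    bounded = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[[v for v in region if v != -1]]
        verts = _order_ccw(verts)
        cells.append(verts)
        on_edge = (
            (np.abs(verts[:, 0] - xmin) < tol) | (np.abs(verts[:, 0] - xmax) < tol)
            | (np.abs(verts[:, 1] - ymin) < tol) | (np.abs(verts[:, 1] - ymax) < tol)
        )
        bounded[i] = not on_edge.any()
    return VoronoiDiagram(seeds=pts, cells=cells, bounded_flags=bounded,
                          window=window)


def vri(diagram: VoronoiDiagram,
        include_unbounded: bool = False,
        cell_center: str = "centroid",
        per_cell_mean: bool = False) -> VriResult:
    """Voronoi regularity index from pooled centroid-to-vertex distances.

    ``cell_center`` selects the reference point per cell: the polygon
    centroid of the clipped cell (default) or the generating seed.  With
    ``per_cell_mean`` the per-cell mean distances, rather than the pooled
    individual distances, enter the mean/SD ratio.
    """
    if cell_center not in {"centroid", "seed"}:
        raise ValueError("cell_center must be 'centroid' or 'seed'")
    idx = np.arange(len(diagram.seeds))
    if not include_unbounded:
        idx = idx[diagram.bounded_flags]
    if len(idx) < 2:
        raise ValueError("need at least 2 included cells for a VRI")

    pooled: list[float] = []
    for i in idx:
        verts = diagram.cells[i]
        center = (polygon_centroid(verts) if cell_center == "centroid"
                  else diagram.seeds[i])
        d = np.hypot(verts[:, 0] - center[0], verts[:, 1] - center[1])
        if per_cell_mean:
            pooled.append(float(d.mean()))
        else:
            pooled.extend(d.tolist())
    distances = np.asarray(pooled)
    d_mean = float(distances.mean())
    d_sd = float(distances.std())
    if d_sd < 1e-12 * max(d_mean, 1e-300):
        return VriResult(distances=distances, d_mean=d_mean, d_sd=d_sd,
                         vri=math.inf, n_cells_used=len(idx),
                         regular_pattern=True, per_cell_mean=per_cell_mean)
    return VriResult(distances=distances, d_mean=d_mean, d_sd=d_sd,
                     vri=d_mean / d_sd, n_cells_used=len(idx),
                     per_cell_mean=per_cell_mean)


def seeds_from_objects(objects: list[SegmentedObject]) -> np.ndarray:
    """Object centroids as Voronoi generators; duplicates merged with warning."""
    if len(objects) < 3:
        raise ValueError("need at least 3 objects to seed a Voronoi diagram")
    pts = np.array([o.centroid for o in objects], dtype=float)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < len(pts):
        warnings.warn("duplicate centroids merged before tessellation")
    if len(uniq) < 3:
        raise ValueError("fewer than 3 distinct centroids")
    return uniq
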