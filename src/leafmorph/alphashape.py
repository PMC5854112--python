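"""Alpha-shape (circumradius-filtered Delaunay) hulls of 2-D point sets.

The alpha shape generalizes the convex hull: triangulate the points, keep
only Delaunay triangles whose circumradius is at most ``alpha``, and take the
union.  For alpha -> infinity the result is the convex hull; for small alpha
the hull hugs concavities such as leaf sinuses and the petiole notch.  The
dissection-index normalization consumes the hull's perimeter and area.

The segment-bounded alpha shape is used as the computable realization of the
arc-bounded alpha hull; in the dense-contour-sampling regime this pipeline
operates in, their perimeters and areas agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .contour import Contour

__all__ = ["AlphaHull", "alpha_shape", "select_alpha"]


@dataclass
class AlphaHull:
    """Alpha-generalized hull of a point set.

    ``boundary`` is a list of closed vertex loops (arrays of point indices
    resolved to coordinates); the first loop is the longest.  ``area`` is the
    total area of the kept triangles, ``perimeter`` the total length of edges
    belonging to exactly one kept triangle.
    """

    alpha: float
    boundary: list[np.ndarray]
    area: float
    perimeter: float
    source_n: int


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each triangle; near-degenerate triangles get +inf."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.hypot(*(b - c).T)
    lb = np.hypot(*(a - c).T)
    lc = np.hypot(*(a - b).T)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    area2 = np.abs(cross)  # 2 * triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[~np.isfinite(r)] = np.inf
    r[area2 == 0.0] = np.inf
    return r


def _triangle_areas(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    return 0.5 * np.abs(cross)


def _stitch_loops(edges: list[tuple[int, int]]) -> list[list[int]]:
    """Stitch boundary edges (unordered index pairs) into closed vertex loops."""
    adj: dict[int, list[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    unused = {tuple(sorted(e)) for e in edges}
    loops = []
    while unused:
        start, nxt = next(iter(unused))
        loop = [start]
        prev, cur = start, nxt
        unused.discard((min(start, nxt), max(start, nxt)))
        while cur != start:
            loop.append(cur)
            candidates = [
                k
                for k in adj[cur]
                if (min(cur, k), max(cur, k)) in unused
            ]
            if not candidates:
                break  # open chain (degenerate); emit as-is
            nxt = candidates[0]
            unused.discard((min(cur, nxt), max(cur, nxt)))
            prev, cur = cur, nxt
        loops.append(loop)
    loops.sort(key=len, reverse=True)
    return loops


def alpha_shape(points: np.ndarray, alpha: float) -> AlphaHull:
    """Compute the alpha shape of a 2-D point set.

    Parameters
    ----------
    points
        ``(n, 2)`` array, n >= 3, not all collinear.
    alpha
        Radius parameter in the same units as the points; ``np.inf`` yields
        the convex hull exactly.

    Raises
    ------
    ValueError
        If the points are collinear, or if ``alpha`` is so small that no
        triangle survives the circumradius filter (the message reports the
        minimal circumradius, i.e. the feature scale).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("points are collinear or otherwise degenerate") from exc
    if len(tri.simplices) == 0:
        raise ValueError("points are collinear: no triangle can be formed")

    radii = _circumradii(pts, tri.simplices)
    if np.isinf(alpha):
        keep = np.ones(len(radii), dtype=bool)
    else:
        keep = radii <= alpha
    if not keep.any():
        raise ValueError(
            f"alpha below feature scale: no triangle survives "
            f"(minimal circumradius = {radii.min():.6g})"
        )
    kept = tri.simplices[keep]
    area = float(_triangle_areas(pts, kept).sum())

    edge_count: dict[tuple[int, int], int] = {}
    for s in kept:
        for i, j in ((s[0], s[1]), (s[1], s[2]), (s[2], s[0])):
            e = (min(i, j), max(i, j))
            edge_count[e] = edge_count.get(e, 0) + 1
    boundary_edges = [e for e, cnt in edge_count.items() if cnt == 1]
    perim = float(
        sum(np.hypot(*(pts[i] - pts[j])) for i, j in boundary_edges)
    )
    loops = [pts[np.asarray(loop)] for loop in _stitch_loops(boundary_edges)]
    return AlphaHull(
        alpha=float(alpha),
        boundary=loops,
        area=area,
        perimeter=perim,
        source_n=len(pts),
    )


def select_alpha(c: Contour) -> float:
    """Default alpha heuristic: 0.2 x the bounding-box diagonal of the contour.

    Scale-equivariant; large enough that the hull bridges tooth sinuses yet
    follows the global blade outline and petiole.  Always overridable.
    """
    return 0.2 * c.bounding_diagonal()
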