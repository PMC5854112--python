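"""Leaf dissection index: isoperimetric shape statistic with alpha-hull
normalization.

``leaf_DI = perimeter^2 / (4 pi area)`` is 1 for a circle and grows with
margin complexity, but also with elongation.  Dividing by the same statistic
computed on the leaf's alpha hull (which bridges the serrations and follows
the petiole) removes the contribution of the global blade shape, so the final
DI is ~1 for a smooth leaf of any proportions and increases with serration
depth.  The final DI is the value compared between genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphashape import alpha_shape, select_alpha
from .contour import Contour, polygon_area, polygon_perimeter, resample_contour

__all__ = ["DissectionRecord", "shape_di", "leaf_di"]

_ISO_EPS = 1e-6


@dataclass
class DissectionRecord:
    """All quantities behind one leaf's dissection index."""

    leaf_DI: float
    ahull_DI: float
    DI: float
    leaf_area: float
    leaf_perimeter: float
    ahull_area: float
    ahull_perimeter: float
    alpha: float
    blade_length: float | None = None
    genotype: str | None = None
    leaf_rank: str | None = None

    def __post_init__(self) -> None:
        if self.leaf_DI < 1.0 - _ISO_EPS or self.ahull_DI < 1.0 - _ISO_EPS:
            raise ValueError(
                "isoperimetric inequality violated: DI terms must be >= 1"
            )


def shape_di(perimeter: float, area: float) -> float:
    """Isoperimetric dissection: perimeter^2 / (4 pi area).

    Equals 1.0 for a circle (isoperimetric identity) and exceeds 1 for every
    other shape.
    """
    if perimeter <= 0 or area <= 0:
        raise ValueError("perimeter and area must be > 0")
    return perimeter**2 / (4.0 * np.pi * area)


def leaf_di(
    c: Contour,
    alpha: float | str = "auto",
    n_hull_points: int = 1024,
    genotype: str | None = None,
    leaf_rank: str | None = None,
    blade_length: float | None = None,
) -> DissectionRecord:
    """Compute the full dissection record of a leaf contour.

    The leaf's perimeter and area come from the contour itself; the alpha
    hull is built on the contour resampled to ``n_hull_points`` equally
    spaced vertices, which decouples hull resolution from pixel size.
    ``alpha="auto"`` uses :func:`leafmorph.alphashape.select_alpha`
    (0.2 x bounding diagonal).
    """
    p = polygon_perimeter(c)
    a = polygon_area(c)
    if alpha == "auto":
        alpha_val = select_alpha(c)
    else:
        alpha_val = float(alpha)
    pts = resample_contour(c, n_hull_points).vertices
    hull = alpha_shape(pts, alpha_val)
    l_di = shape_di(p, a)
    h_di = shape_di(hull.perimeter, hull.area)
    return DissectionRecord(
        leaf_DI=l_di,
        ahull_DI=h_di,
        DI=l_di / h_di,
        leaf_area=a,
        leaf_perimeter=p,
        ahull_area=hull.area,
        ahull_perimeter=hull.perimeter,
        alpha=alpha_val,
        blade_length=blade_length,
        genotype=genotype,
        leaf_rank=leaf_rank,
    )
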