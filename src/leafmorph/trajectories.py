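"""Comparative outputs: mean silhouettes, LOESS developmental trajectories,
blade-length-class t-tests, and phenotype frequency tables.

Blade length serves as the developmental-stage proxy: per-leaf measurements
(dissection index, first-tooth height, reporter signal) are plotted against
blade length per genotype, with a LOESS curve per genotype to aid
interpretation, and compared between genotypes by Student's t-tests within
blade-length classes (defaults 200-400, 400-600, 600-800 µm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contour import Contour, polygon_perimeter
from .landmarks import _orient

__all__ = [
    "LoessCurve",
    "mean_silhouette",
    "loess_fit",
    "bin_and_test",
    "phenotype_frequencies",
    "DEFAULT_CLASS_EDGES",
]

DEFAULT_CLASS_EDGES = (200.0, 400.0, 600.0, 800.0)


@dataclass
class LoessCurve:
    """A fitted local-regression curve evaluated on a grid.

    ``fitted`` is NaN wherever the local neighborhood was insufficient for
    the requested degree (never fabricated); ``n_support`` counts the points
    with non-zero weight at each grid node.
    """

    grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int
    n_support: np.ndarray | None = None


def _turn_angles(v: np.ndarray) -> np.ndarray:
    """Signed turn angle at each vertex of a closed polyline (exact,
    reflection-equivariant up to sign)."""
    e_prev = v - np.roll(v, 1, axis=0)
    e_next = np.roll(v, -1, axis=0) - v
    cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
    dot = (e_prev * e_next).sum(axis=1)
    return np.arctan2(cross, dot)


def _resample_from(v: np.ndarray, s0: float, start_pt: np.ndarray, n: int) -> np.ndarray:
    """Uniform arclength resampling of a closed polyline beginning at the
    exact point ``start_pt`` located at cumulative arclength ``s0``."""
    d = np.roll(v, -1, axis=0) - v
    seg = np.hypot(d[:, 0], d[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    vw = np.vstack([v, v[:1]])
    target = (s0 + np.linspace(0.0, total, n, endpoint=False)) % total
    x = np.interp(target, s, vw[:, 0])
    y = np.interp(target, s, vw[:, 1])
    out = np.column_stack([x, y])
    out[0] = start_pt
    return out


def _align_to_base(
    c: Contour, n_points: int
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Resample a contour to n_points starting at its base end and rigidly
    align: base at the origin, base->apex axis vertical (no scaling).

    All steps are reflection-equivariant on the vertex set, so the aligned
    parameterizations of a leaf and its mirror image correspond exactly
    (which makes the mean of a mirror pair exactly bilaterally symmetric).
    Returns the aligned vertices, the blade length, and the transform
    (base translation and rotation matrix: pt_aligned = (pt - base) @ rot.T).
    """
    o = _orient(c)  # approximate landmarks (resample-based)
    v0 = c.vertices
    n0 = len(v0)

    if o.junctions is not None:
        # refine each junction to the sharpest concave corner of the
        # *original* polygon near the approximate position
        turns = _turn_angles(v0)
        refined = []
        for j in o.junctions:
            approx = o.contour.vertices[j]
            d = np.hypot(*(v0 - approx).T)
            # window small enough to exclude the nearest sinus cusp
            window = d < 0.015 * polygon_perimeter(c)
            if not window.any():
                window = d <= d.min()
            cand = np.where(window)[0]
            refined.append(int(cand[np.argmin(turns[cand])]))
        base_pos = (v0[refined[0]] + v0[refined[1]]) / 2.0
    else:
        base_pos = None  # set below from the principal-axis extreme

    # principal axis of the original vertex set, oriented base -> apex
    centered = v0 - v0.mean(axis=0)
    cov = centered.T @ centered / n0
    _, evecs = np.linalg.eigh(cov)
    u = evecs[:, 1]
    if float(u @ (o.apex.position - o.base.position)) < 0:
        u = -u
    if base_pos is None:
        base_pos = v0[int(np.argmin(centered @ u))]

    ca, sa = u
    rot = np.array([[sa, -ca], [ca, sa]])  # maps u onto (0, 1)
    aligned = (v0 - base_pos) @ rot.T

    # exact start point: the lowest crossing of the vertical axis (x = 0),
    # i.e. the petiole tip (or the base end of a petiole-less blade)
    x = aligned[:, 0]
    xn = np.roll(x, -1)
    crossing = np.where((x <= 0) != (xn <= 0))[0]
    if len(crossing) == 0:
        raise ValueError("aligned contour never crosses its own axis")
    d = np.roll(aligned, -1, axis=0) - aligned
    seg = np.hypot(d[:, 0], d[:, 1])
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    best = None
    for k in crossing:
        t = x[k] / (x[k] - xn[k])
        pt = aligned[k] + t * d[k]
        s0 = s_cum[k] + t * seg[k]
        if best is None or pt[1] < best[0]:
            best = (pt[1], s0, np.array([0.0, pt[1]]))
    _, s0, start_pt = best
    w = _resample_from(aligned, s0, start_pt, n_points)
    bl = float(np.hypot(*(o.apex.position - o.base.position)))
    return w, bl, base_pos, rot


def mean_silhouette(contours: list[Contour], n_points: int = 512) -> Contour:
    """Pointwise mean of base-aligned, arclength-resampled leaf contours.

    Each contour is resampled to ``n_points`` starting at its base landmark
    and rigidly aligned (translation of the base to the origin, rotation of
    the base->apex axis to vertical; no scaling), so the mean preserves
    absolute size differences.  Landmark failure on any contour raises an
    error naming the leaf index.
    """
    if len(contours) == 0:
        raise ValueError("need at least one contour")
    acc = None
    for idx, c in enumerate(contours):
        try:
            w, _, _, _ = _align_to_base(c, n_points)
        except ValueError as exc:
            raise ValueError(f"landmark detection failed on contour {idx}: {exc}") from exc
        acc = w if acc is None else acc + w
    return Contour(acc / len(contours))


def _as_xy(data, x: str = "blade_length", y: str = "value") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return data[x].to_numpy(float), data[y].to_numpy(float)
    x_arr, y_arr = data
    return np.asarray(x_arr, float), np.asarray(y_arr, float)


def loess_fit(
    data,
    span: float = 0.75,
    degree: int = 1,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
) -> LoessCurve:
    """LOESS: locally weighted polynomial regression with tricube weights.

    At each grid point the ``span`` fraction of nearest data points is
    weighted by the tricube kernel ``(1 - (d/dmax)^3)^3`` and a polynomial of
    ``degree`` (1 or 2) is fitted by weighted least squares and evaluated at
    the grid point.  Grid nodes whose window holds fewer than ``degree + 2``
    points are flagged missing (NaN).

    ``data`` is either a DataFrame with ``blade_length``/``value`` columns
    (one genotype at a time) or an ``(x, y)`` pair of arrays.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x, y = _as_xy(data)
    if len(x) < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, float)
    k = max(int(np.ceil(span * len(x))), degree + 1)
    fitted = np.full(len(grid), np.nan)
    n_support = np.zeros(len(grid), dtype=int)
    for g_idx, g in enumerate(grid):
        d = np.abs(x - g)
        if k < len(x):
            dmax = np.partition(d, k - 1)[k - 1]
        else:
            dmax = d.max()
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        mask = w > 0
        n_support[g_idx] = int(mask.sum())
        if n_support[g_idx] < degree + 2:
            continue
        xm = x[mask] - g  # centred design for conditioning
        design = np.vander(xm, degree + 1, increasing=True)
        sw = np.sqrt(w[mask])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[mask] * sw, rcond=None)
        fitted[g_idx] = coef[0]
    return LoessCurve(grid=grid, fitted=fitted, span=span, degree=degree, n_support=n_support)


def bin_and_test(
    data: pd.DataFrame,
    class_edges=DEFAULT_CLASS_EDGES,
    genotypes: tuple[str, str] | None = None,
    equal_var: bool = True,
    value_col: str = "value",
) -> pd.DataFrame:
    """Two-sample t-tests between genotypes within blade-length classes.

    Points are assigned to half-open classes ``[e_i, e_{i+1})``.  The default
    test is the equal-variance (pooled) Student's t-test; Welch's test is
    available with ``equal_var=False``.  Classes with fewer than 2 points in
    either genotype are reported as untestable (``testable=False``, t and p
    NaN), never dropped silently.
    """
    edges = np.asarray(class_edges, float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("class_edges must be increasing with at least 2 values")
    if genotypes is None:
        found = list(pd.unique(data["genotype"]))
        if len(found) != 2:
            raise ValueError(f"expected exactly 2 genotypes, found {found}")
        genotypes = (found[0], found[1])
    g_a, g_b = genotypes
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (data["blade_length"] >= lo) & (data["blade_length"] < hi)
        a = data.loc[sel & (data["genotype"] == g_a), value_col].to_numpy(float)
        b = data.loc[sel & (data["genotype"] == g_b), value_col].to_numpy(float)
        row = {
            "class_lo": lo,
            "class_hi": hi,
            "n_A": len(a),
            "n_B": len(b),
            "mean_A": a.mean() if len(a) else np.nan,
            "mean_B": b.mean() if len(b) else np.nan,
        }
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            row.update(t=float(t), p=float(p), testable=True)
        else:
            row.update(t=np.nan, p=np.nan, testable=False)
        rows.append(row)
    return pd.DataFrame(rows)


def phenotype_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype phenotype frequencies from a (genotype, category, count)
    table; frequencies sum to 1 within each genotype."""
    df = counts.copy()
    if (df["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    totals = df.groupby("genotype")["count"].transform("sum")
    if (totals == 0).any():
        bad = df.loc[totals == 0, "genotype"].unique().tolist()
        raise ValueError(f"zero total count for genotype(s): {bad}")
    df["frequency"] = df["count"] / totals
    return df
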