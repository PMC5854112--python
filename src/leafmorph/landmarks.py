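"""Margin landmarks: base/apex orientation, tooth and sinus detection,
tooth height and blade length.

Teeth are outward projections of the leaf margin; the sinus is the
indentation between consecutive teeth.  Tooth apices are local maxima of the
signed curvature along the margin between base and leaf apex; their flanking
sinuses are the nearest curvature minima on either side.  Tooth height is the
perpendicular distance from the apex to the chord joining its two flanking
sinuses, and blade length is the base-to-apex Euclidean distance (petiole
excluded) — the developmental-stage proxy of the trajectory analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .contour import (
    Contour,
    CurvatureProfile,
    curvature_profile,
    polygon_perimeter,
    resample_contour,
)

__all__ = [
    "Landmark",
    "Tooth",
    "find_base_and_apex",
    "detect_teeth",
    "tooth_height",
    "blade_length",
]

# a petiole is recognised when the neck is narrower than this fraction of the
# maximal blade width
_NECK_FRAC = 0.25
# margin excluded from tooth detection at each side end (fraction of vertices)
_END_EXCLUSION = 0.015


@dataclass
class Landmark:
    kind: str  # base | apex | tooth_apex | sinus
    position: np.ndarray  # (2,) µm
    contour_index: int
    side: str | None = None  # left | right for margin landmarks


@dataclass
class Tooth:
    apex: Landmark
    sinus_prox: Landmark
    sinus_dist: Landmark
    height: float
    rank_from_base: int
    side: str


@dataclass
class _Orientation:
    """Internal: everything downstream landmark steps need."""

    contour: Contour  # uniformly resampled
    profile: CurvatureProfile
    axis: np.ndarray  # unit vector base -> apex
    base: Landmark
    apex: Landmark
    junctions: tuple[int, int] | None  # petiole junction vertex pair (or None)


def _local_minima(kappa: np.ndarray) -> np.ndarray:
    """Indices of strict local minima of a periodic sequence."""
    prev = np.roll(kappa, 1)
    nxt = np.roll(kappa, -1)
    return np.where((kappa < prev) & (kappa <= nxt))[0]


def _orient(c: Contour, n_resample: int = 1024, smooth_sigma: float | None = None) -> _Orientation:
    rc = resample_contour(c, n_resample)
    if smooth_sigma is None:
        # lighter smoothing than the curvature-profile default: landmark
        # positions shift with the smoothing scale, biasing tooth heights
        smooth_sigma = polygon_perimeter(rc) / 500.0
    v = rc.vertices
    n = len(v)
    centered = v - v.mean(axis=0)
    cov = centered.T @ centered / n
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] / max(evals[0], 1e-300) < 1.05**2:
        raise ValueError(
            "cannot orient contour: degenerate principal axes (near-circular shape)"
        )
    u = evecs[:, 1]  # major axis
    minor = evecs[:, 0]
    max_width = float(np.ptp(centered @ minor))

    prof = curvature_profile(rc, smooth_sigma=smooth_sigma)
    kappa = prof.kappa

    # --- petiole neck: the closest pair of strongly concave points ---
    # candidates are minima comparable in depth to the deepest concavity
    # (relative criterion keeps both junction corners even when sinuses are
    # deeper); an absolute guard rejects noise dips on convex outlines
    minima = _local_minima(kappa)
    concave = np.array([], dtype=int)
    if len(minima):
        kmin = float(kappa[minima].min())
        if kmin < -2.0 * np.median(np.abs(kappa)) and kmin < 0:
            concave = minima[kappa[minima] <= 0.3 * kmin]
    junctions = None
    if len(concave) >= 2:
        cand = concave[np.argsort(kappa[concave])][:10]
        best = None
        min_arc = max(3, int(0.02 * n))
        for ai in range(len(cand)):
            for bi in range(ai + 1, len(cand)):
                i, j = int(cand[ai]), int(cand[bi])
                arc = min(abs(i - j), n - abs(i - j))
                if arc < min_arc:
                    continue
                d = float(np.hypot(*(v[i] - v[j])))
                if d >= _NECK_FRAC * max_width:
                    continue
                # among pairs narrow enough to be a neck, take the deepest
                # concave pair (the junction corners), not the narrowest --
                # a tapering petiole is narrower towards its tip
                depth = float(kappa[i] + kappa[j])
                if best is None or depth < best[0]:
                    best = (depth, i, j)
        if best is not None:
            junctions = (best[1], best[2])

    proj = centered @ u
    if junctions is not None:
        i, j = junctions
        base_pos = (v[i] + v[j]) / 2.0
        base_idx = i
        # the blade holds most of the outline: apex lies on the centroid side
        direction = 1.0 if proj.mean() > float((base_pos - v.mean(axis=0)) @ u) else -1.0
        u = u * direction
        rel = (v - base_pos) @ u
        apex_idx = int(np.argmax(rel))
    else:
        skew = float(np.mean(proj**3)) / max(float(np.mean(proj**2)) ** 1.5, 1e-300)
        if abs(skew) > 1e-3:
            # bulk of the outline (the wide part of an ovate blade) sits at the
            # base: orient the axis so the projection skews toward the apex
            if skew < 0:
                u = -u
        elif u[1] < 0 or (u[1] == 0 and u[0] < 0):
            u = -u
        proj = centered @ u
        base_idx = int(np.argmin(proj))
        apex_idx = int(np.argmax(proj))
        base_pos = v[base_idx]

    apex_pos = v[apex_idx]
    axis = apex_pos - base_pos
    axis = axis / np.hypot(*axis)
    base = Landmark("base", np.asarray(base_pos, float), base_idx)
    apex = Landmark("apex", np.asarray(apex_pos, float), apex_idx)
    return _Orientation(rc, prof, axis, base, apex, junctions)


def find_base_and_apex(
    c: Contour, n_resample: int = 1024, smooth_sigma: float | None = None
) -> tuple[Landmark, Landmark]:
    """Locate the blade base and the leaf apex.

    The base is the petiole/lamina junction: the closest pair of strongly
    concave margin points (the neck), collapsed to the neck midpoint, when a
    neck narrower than 25% of the maximal width exists; otherwise the extreme
    vertex along the principal axis on the wide (basal) side of the blade.
    The apex is the margin point farthest from the base along the principal
    axis.  Near-circular contours cannot be oriented and raise ``ValueError``.
    """
    o = _orient(c, n_resample=n_resample, smooth_sigma=smooth_sigma)
    return o.base, o.apex


def _circular_path(i: int, j: int, n: int, through: int) -> list[int]:
    """Index path from i to j (inclusive) passing through vertex `through`."""
    fwd = list(range(i, j + 1)) if i <= j else list(range(i, n)) + list(range(0, j + 1))
    if through in fwd:
        return fwd
    bwd = list(range(i, -1, -1)) + list(range(n - 1, j - 1, -1)) if i < j else list(
        range(i, j - 1, -1)
    )
    return bwd


def tooth_height(t: Tooth) -> float:
    """Perpendicular distance from the tooth apex to the line through its
    flanking sinuses."""
    a = t.apex.position
    p = t.sinus_prox.position
    d = t.sinus_dist.position
    chord = d - p
    nrm = float(np.hypot(*chord))
    if nrm == 0:
        raise ValueError("coincident sinus points")
    rel = a - p
    return float(abs(chord[0] * rel[1] - chord[1] * rel[0]) / nrm)


def blade_length(c: Contour, base: Landmark, apex: Landmark) -> float:
    """Euclidean base-to-apex distance (µm), petiole excluded."""
    return float(np.hypot(*(apex.position - base.position)))


def detect_teeth(
    c: Contour,
    profile: CurvatureProfile | None = None,
    min_prominence: float | None = None,
    min_height: float | None = None,
    n_resample: int = 1024,
    smooth_sigma: float | None = None,
) -> list[Tooth]:
    """Detect marginal teeth between base and apex on each side of the leaf.

    Candidate apices are local curvature maxima on the margin (the leaf apex
    itself and the petiole margin are excluded); flanking sinuses are the
    nearest curvature minima on either side.  Teeth with curvature prominence
    below ``min_prominence`` (default 0.6x the median |kappa| of the contour)
    or height below ``min_height`` (default 1% of blade length) are
    discarded.  Teeth are numbered from the base on each side; an empty list
    is a valid result.
    """
    o = _orient(c, n_resample=n_resample, smooth_sigma=smooth_sigma)
    v = o.contour.vertices
    n = len(v)
    kappa = o.profile.kappa if profile is None else np.asarray(profile.kappa)
    if len(kappa) != n:
        raise ValueError(
            "curvature profile length does not match the resampled contour; "
            "pass profile=None to recompute"
        )
    if min_prominence is None:
        min_prominence = 0.6 * float(np.median(np.abs(kappa)))
    bl = blade_length(c, o.base, o.apex)
    if min_height is None:
        min_height = 0.01 * bl

    if o.junctions is not None:
        j1, j2 = o.junctions
        # margin = the circular path between the junctions containing the apex
        path = _circular_path(j1, j2, n, through=o.apex.contour_index)
        k = path.index(o.apex.contour_index)
        side_paths = [path[: k + 1], list(reversed(path[k:]))]
    else:
        b = o.base.contour_index
        path = _circular_path(b, b - 1 if b > 0 else n - 1, n, through=o.apex.contour_index)
        # whole contour split at base and apex
        k = path.index(o.apex.contour_index)
        side_paths = [path[: k + 1], list(reversed(path[k:]))]

    minima_all = set(_local_minima(kappa).tolist())
    teeth: list[Tooth] = []
    excl = max(3, int(_END_EXCLUSION * n))
    for sp in side_paths:
        if len(sp) <= 2 * excl + 3:
            continue
        interior = sp[excl:-excl]
        ks = kappa[interior]
        peaks, _ = find_peaks(ks, prominence=min_prominence)
        mins_on_path = [q for q, idx in enumerate(sp) if idx in minima_all]
        side_teeth = []
        for pk in peaks:
            q = pk + excl  # position in sp
            prox_cands = [m for m in mins_on_path if m < q]
            dist_cands = [m for m in mins_on_path if m > q]
            if prox_cands:
                qp = prox_cands[-1]
            else:
                qp = int(np.argmin(kappa[sp[:q]])) if q > 0 else 0
            if dist_cands:
                qd = dist_cands[0]
            else:
                tail = kappa[sp[q + 1 :]]
                qd = q + 1 + int(np.argmin(tail)) if len(tail) else len(sp) - 1
            ia, ip, idist = sp[q], sp[qp], sp[qd]
            side = _side_of(v[ia], o)
            ap = Landmark("tooth_apex", v[ia], ia, side)
            spx = Landmark("sinus", v[ip], ip, side)
            sdx = Landmark("sinus", v[idist], idist, side)
            t = Tooth(ap, spx, sdx, 0.0, 0, side)
            try:
                t.height = tooth_height(t)
            except ValueError:
                continue
            if t.height >= min_height:
                side_teeth.append(t)
        for rank, t in enumerate(side_teeth, start=1):
            t.rank_from_base = rank
        teeth.extend(side_teeth)
    return teeth


def _side_of(point: np.ndarray, o: _Orientation) -> str:
    rel = point - o.base.position
    crossp = o.axis[0] * rel[1] - o.axis[1] * rel[0]
    return "left" if crossp > 0 else "right"
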