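"""Parametric synthetic leaves and fluorescence images with exported ground truth.

The generator exists so that every downstream stage (contour measurement,
alpha-hull dissection index, margin-landmark detection, trajectory analysis,
reporter quantification) can be tested against known truth without any
external micrographs.

Leaf model
----------
The blade is an ovate convex outline built from two half-ellipses sharing the
widest chord (placed at 40% of the blade span from the base), attached to a
rectangular petiole with a semicircular tip.  Marginal teeth are raised-cosine
bumps along the arclength of the smooth outline, displaced along the outward
normal; their apices and flanking sinuses are therefore known analytically and
recorded as vertices of the exact polygon.  Optional boundary noise is a
smooth band-limited normal displacement (random low-order Fourier series),
never i.i.d. per-vertex jitter, so the contour stays simple and margins stay
realistic.

All geometry is in µm; :func:`rasterize` is the single bridge to raster space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import LinearRing

from .contour import Contour

__all__ = [
    "LeafParams",
    "LeafTruth",
    "FluorTruth",
    "FlatBackground",
    "PlaneBackground",
    "GaussianBackground",
    "ZoneSpec",
    "NucleusSpec",
    "generate_leaf",
    "rasterize",
    "generate_cohort",
    "generate_fluor_image",
    "random_nuclei",
]

# fraction of the blade span (base to apex) at which the blade is widest
_WIDEST_FRAC = 0.4
# tooth zone along each margin side, as fractions of base-to-apex arclength
_TOOTH_ZONE = (0.10, 0.88)


@dataclass(frozen=True)
class LeafParams:
    """Parameters of one synthetic leaf (all lengths in µm).

    ``tooth_height_frac`` is the tooth height as a fraction of the local blade
    half-width at the tooth position.  ``tooth_width_frac`` is the bump
    support half-width as a fraction of the inter-tooth spacing; at the
    default 0.5 consecutive supports exactly tile the tooth zone, so the
    ground-truth sinus (midpoint between consecutive supports) coincides with
    the curvature minimum used by the landmark detector.
    """

    blade_length: float = 1000.0
    blade_width: float = 340.0
    petiole_length: float = 250.0
    petiole_width: float = 60.0
    n_teeth: int = 3
    tooth_height_frac: float = 0.25
    tooth_width_frac: float = 0.5
    noise_amp: float = 0.0
    seed: int = 0
    n_vertices: int = 4096
    petiole: bool = True

    def validate(self) -> None:
        for name in ("blade_length", "blade_width", "petiole_length", "petiole_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.tooth_height_frac < 1):
            raise ValueError("tooth_height_frac must be in [0, 1)")
        if not (0 < self.tooth_width_frac <= 0.5):
            raise ValueError("tooth_width_frac must be in (0, 0.5]")
        if self.n_teeth < 0:
            raise ValueError("n_teeth must be >= 0")
        if self.noise_amp < 0:
            raise ValueError("noise_amp must be >= 0")
        if self.petiole_width >= self.blade_width:
            raise ValueError("petiole_width must be smaller than blade_width")
        if self.petiole_length <= self.petiole_width / 2:
            raise ValueError("petiole_length must exceed half the petiole width")
        if self.n_vertices < 256:
            raise ValueError("n_vertices must be >= 256")


@dataclass
class ToothRecord:
    """Ground-truth bookkeeping for one generated tooth."""

    side: str  # "right" or "left", looking at the adaxial face, base down
    rank_from_base: int
    apex_index: int
    sinus_prox_index: int
    sinus_dist_index: int
    height: float


@dataclass
class LeafTruth:
    """Exact ground truth for one generated leaf (µm, µm²)."""

    polygon: Contour
    true_area: float
    true_perimeter: float
    tooth_apices: np.ndarray  # (2*n_teeth, 2)
    sinus_points: np.ndarray  # unique sinus positions, margin order
    true_tooth_heights: np.ndarray  # aligned with tooth_apices
    base_point: np.ndarray
    apex_point: np.ndarray
    true_blade_length: float
    teeth: list[ToothRecord] = field(default_factory=list)
    base_indices: tuple[int, int] = (0, 0)  # right / left petiole-junction vertices
    apex_index: int = 0


def _halfwidth(y: np.ndarray | float, total_span: float, half_w: float) -> np.ndarray:
    """Blade half-width at height y above the blade bottom (two half-ellipses)."""
    yc = _WIDEST_FRAC * total_span
    y = np.asarray(y, dtype=float)
    lower = 1.0 - ((yc - y) / yc) ** 2
    upper = 1.0 - ((y - yc) / (total_span - yc)) ** 2
    sq = np.where(y < yc, lower, upper)
    return half_w * np.sqrt(np.clip(sq, 0.0, None))


def _smooth_outline(p: LeafParams) -> tuple[np.ndarray, int, int]:
    """Dense smooth blade+petiole outline, CCW, starting at the right
    petiole junction.  Returns (vertices, apex_dense_idx, leftj_dense_idx)."""
    W2 = p.blade_width / 2.0
    pw2 = p.petiole_width / 2.0
    if p.petiole:
        # blade span solved so that base(neck midpoint)-to-apex distance equals
        # blade_length exactly: y0 = c*span*(1 - sqrt(1 - (pw/W)^2))
        beta = 1.0 - np.sqrt(1.0 - (pw2 / W2) ** 2)
        span = p.blade_length / (1.0 - _WIDEST_FRAC * beta)
    else:
        beta = 0.0
        span = p.blade_length
    yc = _WIDEST_FRAC * span
    y0 = yc * beta

    m = 3000  # dense samples per piece
    # right margin, lower half-ellipse: x = W2 sin(phi), y = yc (1 - cos(phi))
    phi0 = np.arccos(1.0 - y0 / yc)
    phi = np.linspace(phi0, np.pi / 2, m)
    low = np.column_stack([W2 * np.sin(phi), yc * (1.0 - np.cos(phi))])
    # right margin, upper half-ellipse: x = W2 cos(psi), y = yc + (span-yc) sin(psi)
    psi = np.linspace(0.0, np.pi / 2, m)
    up = np.column_stack([W2 * np.cos(psi), yc + (span - yc) * np.sin(psi)])
    right = np.vstack([low, up[1:]])
    # left margin: mirror, traversed apex -> left junction (still CCW)
    left = np.column_stack([-right[::-1, 0], right[::-1, 1]])
    blade = np.vstack([right, left[1:]])
    apex_dense = len(right) - 1

    if not p.petiole:
        # full convex oval: drop the duplicate base vertex at the end
        outline = blade[:-1] if np.allclose(blade[-1], blade[0]) else blade
        return outline, apex_dense, len(outline) - 1

    # petiole: straight sides + semicircular tip, CCW through the bottom
    y_cap = y0 - p.petiole_length + pw2
    side_l = np.column_stack([np.full(m, -pw2), np.linspace(y0, y_cap, m)])
    ang = np.linspace(np.pi, 2.0 * np.pi, m)
    cap = np.column_stack([pw2 * np.cos(ang), y_cap + pw2 * np.sin(ang)])
    side_r = np.column_stack([np.full(m, pw2), np.linspace(y_cap, y0, m)])
    outline = np.vstack([blade, side_l[1:], cap[1:], side_r[1:-1]])
    leftj_dense = len(blade) - 1
    return outline, apex_dense, leftj_dense


def _resample_open(v: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Uniform-arclength resampling of a closed polyline given with its first
    vertex only once.  Returns (vertices, arclength_at_vertex, total)."""
    d = np.roll(v, -1, axis=0) - v
    s = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
    total = s[-1]
    vw = np.vstack([v, v[:1]])
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, vw[:, 0])
    y = np.interp(target, s, vw[:, 1])
    return np.column_stack([x, y]), target, total


def _dense_arclength_at(v: np.ndarray, idx: int) -> float:
    d = np.diff(v[: idx + 1], axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _point_line_distance(pt: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    nrm = np.hypot(*ab)
    if nrm == 0:
        raise ValueError("coincident sinus points: tooth chord is degenerate")
    rel = pt - a
    return float(abs(ab[0] * rel[1] - ab[1] * rel[0]) / nrm)


def generate_leaf(params: LeafParams) -> tuple[Contour, LeafTruth]:
    """Generate one leaf silhouette and its exact ground truth.

    Identical ``params`` (including ``seed``) reproduce the output
    bit-for-bit.  Parameter combinations whose tooth displacement would
    self-intersect the outline are rejected with a diagnostic.
    """
    params.validate()
    dense, apex_d, leftj_d = _smooth_outline(params)
    s_apex = _dense_arclength_at(dense, apex_d)
    s_leftj = _dense_arclength_at(dense, leftj_d)
    base, s_grid, total = _resample_open(dense, params.n_vertices)
    n = params.n_vertices
    ds = total / n

    # outward normals of the smooth outline (CCW -> outward is right of travel);
    # the normal field is taken from a lightly smoothed copy so that it rotates
    # smoothly through the petiole-junction corners — otherwise a noise
    # displacement larger than the corner radius folds the outline
    from scipy.ndimage import gaussian_filter1d

    sigma_arc = max(4.0 * ds, 3.0 * params.noise_amp)
    sm = np.column_stack(
        [
            gaussian_filter1d(base[:, 0], sigma_arc / ds, mode="wrap"),
            gaussian_filter1d(base[:, 1], sigma_arc / ds, mode="wrap"),
        ]
    )
    t = (np.roll(sm, -1, axis=0) - np.roll(sm, 1, axis=0)) / 2.0
    tn = np.hypot(t[:, 0], t[:, 1])
    normals = np.column_stack([t[:, 1], -t[:, 0]]) / tn[:, None]

    W2 = params.blade_width / 2.0
    if params.petiole:
        beta = 1.0 - np.sqrt(1.0 - (params.petiole_width / params.blade_width) ** 2)
        span = params.blade_length / (1.0 - _WIDEST_FRAC * beta)
    else:
        span = params.blade_length

    lo, hi = _TOOTH_ZONE
    disp = np.zeros(n)
    teeth: list[ToothRecord] = []
    idx_of = lambda s: int(np.clip(round(s / ds), 0, n - 1))

    def _add_side(side: str, s_from_base, nteeth: int) -> None:
        # s_from_base maps a distance-from-base along this margin side to a
        # global arclength position on the contour
        if nteeth == 0:
            return
        S = s_apex if side == "right" else (s_leftj - s_apex)
        spacing = (hi - lo) * S / nteeth
        # support width capped at the 3-teeth spacing so that sparse margins
        # still carry locally sharp, detectable teeth
        w_sup = params.tooth_width_frac * min(spacing, (hi - lo) * S / 3.0)
        for j in range(nteeth):
            c_j = lo * S + (j + 0.5) * spacing
            ci = idx_of(s_from_base(c_j))
            # ground-truth sinuses sit at the bump support edges — the
            # curvature minima of the final outline (at the default tiling
            # these are also the midpoints between consecutive tooth centres)
            pi = idx_of(s_from_base(c_j - w_sup))
            di = idx_of(s_from_base(c_j + w_sup))
            h = params.tooth_height_frac * _halfwidth(base[ci, 1], span, W2)
            u = s_grid - s_from_base(c_j) if side == "right" else None
            # raised-cosine bump around the snapped centre, in global arclength
            center_s = s_grid[ci]
            u = np.abs(s_grid - center_s)
            sel = u <= w_sup
            disp[sel] += 0.5 * h * (1.0 + np.cos(np.pi * u[sel] / w_sup))
            teeth.append(ToothRecord(side, j + 1, ci, pi, di, float(h)))

    _add_side("right", lambda d: d, params.n_teeth)
    _add_side("left", lambda d: s_leftj - d, params.n_teeth)

    if params.noise_amp > 0:
        rng = np.random.default_rng(params.seed)
        k = np.arange(1, 11)[:, None]  # band limit: harmonics 1..10
        phase = 2.0 * np.pi * s_grid[None, :] / total
        g = (
            rng.normal(size=(10, 1)) * np.cos(k * phase)
            + rng.normal(size=(10, 1)) * np.sin(k * phase)
        ).sum(axis=0)
        g *= params.noise_amp / np.sqrt(np.mean(g**2))
        disp = disp + g

    verts = base + disp[:, None] * normals
    ring = LinearRing(verts)
    if not ring.is_simple:
        raise ValueError(
            "generated outline self-intersects; reduce tooth_height_frac "
            "relative to tooth_width_frac (or noise_amp)"
        )

    contour = Contour(verts.copy())
    v = contour.vertices  # CCW-normalised (construction is already CCW)
    seg = np.roll(v, -1, axis=0) - v

    apex_idx = idx_of(s_apex)
    leftj_idx = idx_of(s_leftj)
    base_point = (v[0] + v[leftj_idx]) / 2.0
    apex_point = v[apex_idx].copy()

    heights = []
    apices = []
    sinus_idx: list[int] = []
    for tr in teeth:
        a, sp, sd = v[tr.apex_index], v[tr.sinus_prox_index], v[tr.sinus_dist_index]
        tr.height = _point_line_distance(a, sp, sd)
        heights.append(tr.height)
        apices.append(a)
        for i in (tr.sinus_prox_index, tr.sinus_dist_index):
            if i not in sinus_idx:
                sinus_idx.append(i)

    truth = LeafTruth(
        polygon=contour,
        true_area=contour.area,
        true_perimeter=contour.perimeter,
        tooth_apices=np.array(apices).reshape(-1, 2),
        sinus_points=v[sinus_idx].reshape(-1, 2) if sinus_idx else np.empty((0, 2)),
        true_tooth_heights=np.asarray(heights, dtype=float),
        base_point=base_point,
        apex_point=apex_point,
        true_blade_length=float(np.hypot(*(apex_point - base_point))),
        teeth=teeth,
        base_indices=(0, leftj_idx),
        apex_index=apex_idx,
    )
    return contour, truth


def rasterize(contour: Contour, pixel_size: float, pad: int = 2) -> np.ndarray:
    """Rasterize a contour: foreground pixels are those whose centres lie
    inside the polygon, with >= ``pad`` pixels of background on all sides.

    Uses the package raster convention (x = col*p, y = (H-row)*p up to a
    translation placing the shape inside the canvas).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    v = contour.vertices
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    if pixel_size > min(hi - lo):
        raise ValueError(
            f"pixel_size {pixel_size} exceeds the contour bounding box {hi - lo}"
        )
    w_px = int(np.ceil((hi[0] - lo[0]) / pixel_size)) + 2 * pad + 1
    h_px = int(np.ceil((hi[1] - lo[1]) / pixel_size)) + 2 * pad + 1
    x_off = lo[0] - pad * pixel_size
    y_off = lo[1] - pad * pixel_size
    cols = np.arange(w_px)
    rows = np.arange(h_px)
    xs = x_off + cols * pixel_size
    ys = y_off + (h_px - rows) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = MplPath(v).contains_points(pts).reshape(h_px, w_px)
    return mask


def generate_cohort(
    base: LeafParams,
    n_leaves: int,
    blade_range: tuple[float, float],
    genotype_tooth_scale: float = 1.0,
    seed: int = 0,
    genotype: str = "genotype",
    height_jitter_sd: float = 0.08,
) -> list[tuple[Contour, LeafTruth, dict]]:
    """Generate a developmental series of leaves spanning ``blade_range``.

    Blade lengths are drawn uniformly over ``blade_range``; blade width,
    petiole dimensions and noise amplitude scale isometrically with blade
    length so that proportions and *relative* boundary noise are stage
    invariant.  ``tooth_height_frac`` is multiplied by
    ``genotype_tooth_scale`` (values < 1 emulate a smooth-margin genotype)
    and by a per-leaf lognormal jitter (sd ``height_jitter_sd`` on the log
    scale) emulating biological variability.  Metadata records the genotype
    label, leaf id and true blade length.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if not blade_range[1] > blade_range[0] > 0:
        raise ValueError("blade_range must be increasing and positive")
    if genotype_tooth_scale < 0:
        raise ValueError("genotype_tooth_scale must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_leaves):
        bl = float(rng.uniform(*blade_range))
        f = bl / base.blade_length
        jit = float(np.exp(rng.normal(0.0, height_jitter_sd))) if height_jitter_sd else 1.0
        leaf_seed = int(rng.integers(0, 2**31 - 1))
        thf = min(base.tooth_height_frac * genotype_tooth_scale * jit, 0.9)
        p = replace(
            base,
            blade_length=bl,
            blade_width=base.blade_width * f,
            petiole_length=base.petiole_length * f,
            petiole_width=base.petiole_width * f,
            noise_amp=base.noise_amp * f,
            tooth_height_frac=thf,
            seed=leaf_seed,
        )
        contour, truth = generate_leaf(p)
        meta = {
            "genotype": genotype,
            "leaf_id": f"{genotype}_{i:03d}",
            "blade_length": truth.true_blade_length,
            "params": p,
        }
        out.append((contour, truth, meta))
    return out


# ---------------------------------------------------------------------------
# fluorescence images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlatBackground:
    level: float = 100.0

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        return np.full(shape, float(self.level))


@dataclass(frozen=True)
class PlaneBackground:
    """Linear intensity ramp: level at the image centre plus per-pixel slopes."""

    level: float = 100.0
    slope_row: float = 0.0
    slope_col: float = 0.0

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        r, c = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return (
            self.level
            + self.slope_row * (r - shape[0] / 2.0)
            + self.slope_col * (c - shape[1] / 2.0)
        )


@dataclass(frozen=True)
class GaussianBackground:
    """Broad Gaussian mound on a flat pedestal."""

    level: float = 100.0
    amplitude: float = 50.0
    center: tuple[float, float] = (0.0, 0.0)  # (row, col)
    sigma: float = 100.0

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        r, c = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        d2 = (r - self.center[0]) ** 2 + (c - self.center[1]) ** 2
        return self.level + self.amplitude * np.exp(-d2 / (2.0 * self.sigma**2))


@dataclass(frozen=True)
class ZoneSpec:
    """A compact above-background signal zone: a disk of uniform amplitude."""

    center: tuple[float, float]  # (row, col)
    radius: float
    amplitude: float


@dataclass(frozen=True)
class NucleusSpec:
    """A point-like nucleus: an isotropic Gaussian spot."""

    center: tuple[float, float]  # (row, col)
    peak: float
    sigma: float = 2.0


@dataclass
class FluorTruth:
    """Ground truth for one synthetic fluorescence image."""

    zone_mask: np.ndarray
    zone_total_signal: float
    background_field: np.ndarray
    nuclei: list[tuple[np.ndarray, float]]  # (centroid (row,col), true mean intensity)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    r, c = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2


def generate_fluor_image(
    shape: tuple[int, int],
    background,
    zone: ZoneSpec | None = None,
    nuclei: list[NucleusSpec] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
    measure_radius_factor: float = 2.0,
) -> tuple[np.ndarray, FluorTruth]:
    """Compose background + signal zone + nuclei spots (+ Gaussian noise).

    Truth records the noise-free background field, the zone footprint and its
    total above-background signal, and for each nucleus its centroid and the
    mean of the *noise-free* composite image over a disk of radius
    ``measure_radius_factor * sigma`` — i.e. what an ideal disk measurement
    would return.
    """
    shape = (int(shape[0]), int(shape[1]))
    bg = np.asarray(background.render(shape), dtype=float)
    clean = bg.copy()

    if zone is not None:
        zr, zc = zone.center
        if not (
            zone.radius <= zr <= shape[0] - 1 - zone.radius
            and zone.radius <= zc <= shape[1] - 1 - zone.radius
        ):
            raise ValueError("signal zone extends outside the image")
        zone_mask = _disk_mask(shape, zone.center, zone.radius)
        clean[zone_mask] += zone.amplitude
        zone_total = float(zone.amplitude * zone_mask.sum())
    else:
        zone_mask = np.zeros(shape, dtype=bool)
        zone_total = 0.0

    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for nuc in nuclei:
        nr, nc = nuc.center
        if not (0 <= nr <= shape[0] - 1 and 0 <= nc <= shape[1] - 1):
            raise ValueError(f"nucleus centroid {nuc.center} lies outside the image")
        d2 = (rr - nr) ** 2 + (cc - nc) ** 2
        clean += nuc.peak * np.exp(-d2 / (2.0 * nuc.sigma**2))

    truth_nuclei = []
    for nuc in nuclei:
        disk = _disk_mask(shape, nuc.center, measure_radius_factor * nuc.sigma)
        truth_nuclei.append((np.asarray(nuc.center, float), float(clean[disk].mean())))

    image = clean
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = clean + rng.normal(0.0, noise_sigma, size=shape)

    truth = FluorTruth(
        zone_mask=zone_mask,
        zone_total_signal=zone_total,
        background_field=bg,
        nuclei=truth_nuclei,
    )
    return image, truth


def random_nuclei(
    shape: tuple[int, int],
    n: int,
    rng: np.random.Generator,
    peaks: np.ndarray | None = None,
    sigma: float = 2.0,
    min_separation: float = 12.0,
    margin: float = 10.0,
) -> list[NucleusSpec]:
    """Place ``n`` non-overlapping nuclei uniformly at random (rejection
    sampling); peaks default to a descending 20..1-style ramp scaled to n."""
    if peaks is None:
        peaks = np.linspace(n, 1, n) * 10.0
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        cand = np.array(
            [
                rng.uniform(margin, shape[0] - 1 - margin),
                rng.uniform(margin, shape[1] - 1 - margin),
            ]
        )
        if all(np.hypot(*(cand - c)) >= min_separation for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place nuclei with requested separation")
    return [
        NucleusSpec(center=(float(c[0]), float(c[1])), peak=float(p), sigma=sigma)
        for c, p in zip(centers, peaks)
    ]
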