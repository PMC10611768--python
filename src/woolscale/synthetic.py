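"""Seeded synthetic fixtures: fibre rasters with exact ground-truth scale
geometry, Fickian dye-uptake series, and per-fibre measurement tables.

Every generator is deterministic for a fixed seed, so downstream measurement
and fitting code can be validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from scipy.special import jn_zeros
from shapely.geometry import LineString, box
from shapely.ops import unary_union
from skimage.draw import line as draw_line
from skimage.morphology import dilation, footprint_rectangle

from .kinetics import DyebathRecord, UptakeSeries
from .morphometry import FibreImage, ScalePattern

__all__ = [
    "ImageSpec",
    "GroundTruth",
    "KineticsSpec",
    "generate_fibre_image",
    "generate_uptake_series",
    "generate_measurement_table",
    "cylinder_uptake_fraction",
    "hill_uptake_fraction",
]

BACKGROUND_GREY = 30.0
BODY_GREY = 128.0
BOUNDARY_GREY = 255.0


@dataclass(frozen=True)
class ImageSpec:
    """Geometry of one synthetic fibre image."""

    diameter_um: float
    length_um: float = 520.0
    um_per_px: float = 0.2
    pattern: ScalePattern = ScalePattern.CORONAL
    scales_per_100um: float = 6.0
    edge_width_px: int = 2
    noise_sd: float = 0.0
    seed: int = 0
    arc_sagitta_frac: float = 0.15  # coronal arc bow, as a fraction of diameter

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")
        if self.scales_per_100um < 1:
            raise ValueError("scales_per_100um must be >= 1")
        if self.length_um < 100:
            raise ValueError("length_um must cover at least one 100 um window")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.edge_width_px < 1:
            raise ValueError("edge_width_px must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for the drawn geometry, per full 100 µm window."""

    boundary_length_per_window: list[float]
    scale_count_per_window: list[float]
    true_diameter_um: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.boundary_length_per_window):
            raise ValueError("boundary lengths must be non-negative")
        for c in self.scale_count_per_window:
            if c < 0 or abs(c * 2 - round(c * 2)) > 1e-9:
                raise ValueError("scale counts must be non-negative multiples of 0.5")


@dataclass(frozen=True)
class KineticsSpec:
    """Parameters of one synthetic dye-uptake series."""

    D_true: float  # cm^2 s^-1
    radius_cm: float
    Me: float = 15.0  # mg g^-1
    times_min: tuple[float, ...] = tuple(float(t) for t in range(5, 245, 5))
    noise_sd: float = 0.0
    model: str = "hill_early"  # or "cylinder_series"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be non-negative")
        if not self.radius_cm > 0:
            raise ValueError("radius_cm must be positive")
        if not self.Me > 0:
            raise ValueError("Me must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.times_min, dtype=float)
        if t.size == 0:
            raise ValueError("times_min must be non-empty")
        if (t < 0).any() or (np.diff(t) <= 0).any():
            raise ValueError("times_min must be non-negative and strictly increasing")
        if self.model not in ("hill_early", "cylinder_series"):
            raise ValueError(f"unknown kinetics model {self.model!r}")


# ---------------------------------------------------------------------------
# fibre image generation


def _coronal_arcs(spec: ImageSpec, y_lo: float, y_hi: float) -> list[LineString]:
    """Transverse circular arcs at spacing 100/scales_per_100um µm, sampled
    as polylines with endpoints exactly on the band edges."""
    d = y_hi - y_lo
    yc = 0.5 * (y_lo + y_hi)
    spacing = 100.0 / spec.scales_per_100um
    sag = spec.arc_sagitta_frac * d
    lines = []
    x = spacing / 2.0
    while x < spec.length_um:
        if sag <= 1e-12:
            lines.append(LineString([(x, y_lo), (x, y_hi)]))
        else:
            h = d / 2.0
            radius = (sag * sag + h * h) / (2.0 * sag)
            cx = x + sag - radius
            phi = np.arcsin(h / radius)
            theta = np.linspace(-phi, phi, 33)
            pts = np.column_stack([cx + radius * np.cos(theta), yc + radius * np.sin(theta)])
            lines.append(LineString(pts))
        x += spacing
    return lines


def _diagonal_bands(spec: ImageSpec, y_lo: float, y_hi: float) -> list[LineString]:
    """45° diagonal boundaries at axial spacing 100/scales_per_100um µm."""
    d = y_hi - y_lo
    spacing = 100.0 / spec.scales_per_100um
    lines = []
    c = spacing / 2.0 - d
    while c < spec.length_um:
        seg = LineString([(c, y_lo), (c + d, y_hi)])
        clipped = seg.intersection(box(0.0, y_lo, spec.length_um, y_hi))
        if not clipped.is_empty and clipped.length > 0:
            lines.append(clipped)
        c += spacing
    return lines


def _reticulate_edges(
    spec: ImageSpec, y_lo: float, y_hi: float, rng: np.random.Generator
) -> list[LineString]:
    """Nearest-seed tessellation edges from a jittered point grid whose mean
    cell density matches scales_per_100um."""
    d = y_hi - y_lo
    length = spec.length_um
    cell_area = 100.0 * d / spec.scales_per_100um
    a = np.sqrt(cell_area)
    ny = max(1, int(round(d / a)))
    nx = max(2, int(round(spec.scales_per_100um * length / 100.0 / ny)))
    sx, sy = length / nx, d / ny
    gx, gy = np.meshgrid(
        (np.arange(nx) + 0.5) * sx, y_lo + (np.arange(ny) + 0.5) * sy
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts[:, 0] += rng.uniform(-0.35, 0.35, pts.shape[0]) * sx
    pts[:, 1] += rng.uniform(-0.35, 0.35, pts.shape[0]) * sy
    n_interior = pts.shape[0]

    # guard ring so every interior cell is finite
    pad = 2.0 * max(sx, sy)
    step = max(min(sx, sy), 1e-6)
    xs = np.arange(-pad, length + pad + step, step)
    ys = np.arange(y_lo - pad, y_hi + pad + step, step)
    ring = (
        [(x, y_lo - pad) for x in xs]
        + [(x, y_hi + pad) for x in xs]
        + [(-pad, y) for y in ys]
        + [(length + pad, y) for y in ys]
    )
    allpts = np.vstack([pts, np.asarray(ring)])

    vor = Voronoi(allpts)
    band = box(0.0, y_lo, length, y_hi)
    lines = []
    for (p, q), (v0, v1) in zip(vor.ridge_points, vor.ridge_vertices):
        if v0 < 0 or v1 < 0:
            continue
        if p >= n_interior and q >= n_interior:
            continue
        seg = LineString([vor.vertices[v0], vor.vertices[v1]])
        clipped = seg.intersection(band)
        if not clipped.is_empty and clipped.length > 0:
            if clipped.geom_type == "MultiLineString":
                lines.extend(clipped.geoms)
            else:
                lines.append(clipped)
    return lines


def _ground_truth(
    lines: list[LineString],
    y_lo: float,
    y_hi: float,
    length_um: float,
    diameter_um: float,
) -> GroundTruth:
    n_win = int(np.floor(length_um / 100.0 + 1e-9))
    merged = unary_union(lines) if lines else None
    band = box(0.0, y_lo, length_um, y_hi)
    if merged is not None and not merged.is_empty:
        # split the band by the drawn boundaries; the hair-width buffer makes
        # the split robust to endpoints that only touch the band edge
        pieces = band.difference(merged.buffer(1e-6, cap_style="flat"))
        cells = list(pieces.geoms) if pieces.geom_type == "MultiPolygon" else [pieces]
    else:
        cells = [band]

    eps = 1e-9
    lengths, counts = [], []
    for w in range(n_win):
        a, b = 100.0 * w, 100.0 * (w + 1)
        win = box(a, y_lo - 1.0, b, y_hi + 1.0)
        seg_len = 0.0
        if merged is not None and not merged.is_empty:
            seg_len = merged.intersection(win).length
        lengths.append(float(seg_len))
        full = 0
        partial = 0
        for cell in cells:
            minx, _, maxx, _ = cell.bounds
            if minx >= b - eps or maxx <= a + eps:
                continue
            at_frame = minx <= eps or maxx >= length_um - eps
            if not at_frame and minx > a + eps and maxx < b - eps:
                full += 1
            else:
                partial += 1
        counts.append(full + 0.5 * partial)
    return GroundTruth(
        boundary_length_per_window=lengths,
        scale_count_per_window=counts,
        true_diameter_um=diameter_um,
    )


def generate_fibre_image(spec: ImageSpec) -> tuple[FibreImage, GroundTruth]:
    """Render one straight horizontal fibre with drawn scale boundaries.

    Grey levels before noise: background 30, fibre body 128, boundaries 255.
    The returned :class:`GroundTruth` holds the exact analytic polyline
    length and the full/partial (1 / 0.5) scale count per 100 µm window,
    computed from the drawn geometry before rasterization.
    """
    upp = spec.um_per_px
    band_px = int(round(spec.diameter_um / upp))
    if band_px < 3:
        raise ValueError("fibre too narrow to rasterize at this um_per_px")
    spacing_px = (100.0 / spec.scales_per_100um) / upp
    if spec.pattern is ScalePattern.RETICULATE:
        cell_px = np.sqrt(100.0 * spec.diameter_um / spec.scales_per_100um) / upp
        spacing_px = cell_px
    if spacing_px < 2 * spec.edge_width_px:
        raise ValueError("scale spacing below 2x edge width: unresolvable")

    w_px = int(round(spec.length_um / upp))
    margin_px = max(10, band_px // 4)
    h_px = band_px + 2 * margin_px
    if band_px > h_px:
        raise ValueError("fibre wider than image")
    y_lo = margin_px * upp
    y_hi = (margin_px + band_px) * upp
    true_d = band_px * upp

    rng = np.random.default_rng(spec.seed)
    if spec.pattern is ScalePattern.CORONAL:
        lines = _coronal_arcs(spec, y_lo, y_hi)
    elif spec.pattern is ScalePattern.CORONAL_RETICULATE:
        lines = _diagonal_bands(spec, y_lo, y_hi)
    else:
        lines = _reticulate_edges(spec, y_lo, y_hi, rng)

    gt = _ground_truth(lines, y_lo, y_hi, spec.length_um, true_d)

    img = np.full((h_px, w_px), BACKGROUND_GREY)
    r_lo, r_hi = margin_px, margin_px + band_px - 1
    img[r_lo : r_hi + 1, :] = BODY_GREY

    canvas = np.zeros((h_px, w_px), dtype=bool)
    for ls in lines:
        xy = np.asarray(ls.coords)
        cc_f = np.clip(np.floor(xy[:, 0] / upp).astype(int), 0, w_px - 1)
        rr_f = np.clip(np.floor(xy[:, 1] / upp).astype(int), r_lo, r_hi)
        for i in range(len(xy) - 1):
            rr, cc = draw_line(rr_f[i], cc_f[i], rr_f[i + 1], cc_f[i + 1])
            canvas[rr, cc] = True
    if spec.edge_width_px > 1:
        canvas = dilation(
            canvas, footprint_rectangle((spec.edge_width_px, spec.edge_width_px))
        )
    band_rows = np.zeros_like(canvas)
    band_rows[r_lo : r_hi + 1, :] = True
    img[canvas & band_rows] = BOUNDARY_GREY

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 255.0)

    fid = f"synthetic-{spec.pattern.value}-d{spec.diameter_um:g}-s{spec.seed}"
    return FibreImage(pixels=img, um_per_px=upp, id=fid), gt


# ---------------------------------------------------------------------------
# dye-uptake kinetics


def hill_uptake_fraction(t_s: np.ndarray, D: float, radius_cm: float) -> np.ndarray:
    """Early-phase relative uptake 4*sqrt(D*t/(pi*r^2)), capped at 1."""
    t_s = np.asarray(t_s, dtype=float)
    return np.minimum(1.0, 4.0 * np.sqrt(D * t_s / (np.pi * radius_cm**2)))


def cylinder_uptake_fraction(
    t_s: np.ndarray, D: float, radius_cm: float, tol: float = 1e-10
) -> np.ndarray:
    """Exact relative uptake for an infinite cylinder at constant surface
    concentration: 1 - sum_n (4/(r^2 a_n^2)) exp(-D a_n^2 t), with a_n * r the
    zeros of J0.  The series is extended until the first truncated term is
    below ``tol`` for every positive time."""
    t_s = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t_s)
    pos = t_s > 0
    if D == 0 or not pos.any():
        return out
    tmin = t_s[pos].min()
    n = 128
    while True:
        zeros = jn_zeros(0, n)
        an2 = (zeros / radius_cm) ** 2
        if 4.0 / (radius_cm**2 * an2[-1]) * np.exp(-D * an2[-1] * tmin) < tol or n >= 2**17:
            break
        n *= 2
    series = (4.0 / (radius_cm**2 * an2))[None, :] * np.exp(
        -np.outer(t_s[pos], D * an2)
    )
    out[pos] = 1.0 - series.sum(axis=1)
    return np.clip(out, 0.0, 1.0)


def generate_uptake_series(spec: KineticsSpec) -> UptakeSeries:
    """Simulate a dye-bath uptake record from a Fickian cylinder model.

    ``hill_early`` uses the early-phase square-root law; ``cylinder_series``
    the exact Bessel-series solution.  Gaussian noise of sd ``noise_sd``
    (mg/g) is added and the result clipped to [0, Me].
    """
    t_min = np.asarray(spec.times_min, dtype=float)
    t_s = t_min * 60.0
    if spec.model == "hill_early":
        frac = hill_uptake_fraction(t_s, spec.D_true, spec.radius_cm)
    else:
        frac = cylinder_uptake_fraction(t_s, spec.D_true, spec.radius_cm)
    mt = spec.Me * frac
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mt = mt + rng.normal(0.0, spec.noise_sd, mt.shape)
    mt = np.clip(mt, 0.0, spec.Me)

    w, v = 1.0, 50.0
    c0 = max(0.4, 2.0 * spec.Me * w / v)
    bath = DyebathRecord(
        C0=c0, V=v, W=w, radius_cm=spec.radius_cm, calibration=(1.0, 0.0)
    )
    return UptakeSeries(
        bath=bath,
        times_min=tuple(t_min.tolist()),
        mt_mg_g=tuple(float(m) for m in mt),
        replicate_id=f"sim-{spec.model}-{spec.seed}",
    )


# ---------------------------------------------------------------------------
# per-fibre measurement tables


def generate_measurement_table(
    n_fibres: int,
    diameter_range: tuple[float, float],
    model,
    noise_sd: float,
    seed: int,
    mean_scale_perimeter_um: float = 48.0,
):
    """Sample a per-fibre (diameter, perimeter, scale count) table from a
    quadratic-through-origin perimeter model plus Gaussian noise.

    ``model`` is either a fitted perimeter model (with ``a``/``b``
    attributes) or a plain ``(a, b)`` pair.
    """
    import pandas as pd

    if n_fibres < 3:
        raise ValueError("n_fibres must be >= 3")
    lo, hi = diameter_range
    if not (0 < lo <= hi):
        raise ValueError("invalid diameter range")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    a = getattr(model, "a", None)
    b = getattr(model, "b", None)
    if a is None:
        a, b = model
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, n_fibres)
    y = a * x + b * x * x
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_fibres)
    y = np.clip(y, 0.0, None)
    counts = np.round(y / mean_scale_perimeter_um * 2.0) / 2.0
    return pd.DataFrame(
        {
            "diameter_um": x,
            "perimeter_per_100um": y,
            "scale_count": counts,
        }
    )
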