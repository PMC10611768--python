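"""Fibre scale morphometry from grayscale micrographs.

Measures, for a single straight fibre imaged against a darker background:

* the fibre diameter (mean of 50 chords perpendicular to the fibre axis),
* the total scale-boundary perimeter per 100 µm axial window,
* the visible-scale count per window (full scale = 1, partial = 0.5),
* the scale perimeter index (SPI = perimeter per 100 µm / diameter),
* the diameter-based scale-pattern class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, gaussian, threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "ScalePattern",
    "FibreImage",
    "FibreAxis",
    "WindowMeasurement",
    "FibreMeasurement",
    "detect_fibre",
    "segment_scale_edges",
    "measure_windows",
    "compute_spi",
    "classify_pattern",
    "measure_fibre",
    "skeleton_length_px",
    "skeleton_edges",
]

SQRT2 = float(np.sqrt(2.0))


class ScalePattern(str, Enum):
    """Scale arrangement classes, assigned from fibre diameter."""

    CORONAL = "coronal"
    CORONAL_RETICULATE = "coronal_reticulate"
    RETICULATE = "reticulate"


@dataclass(frozen=True)
class FibreImage:
    """A grayscale raster with a physical scale.

    ``um_per_px`` is mandatory: all downstream quantities are physical.
    """

    pixels: np.ndarray
    um_per_px: float
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class FibreAxis:
    """Least-squares fibre axis: a point (row, col) and a unit direction."""

    centroid_rc: tuple[float, float]
    direction_rc: tuple[float, float]
    length_px: float

    def axial_coords(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Signed axial position (px) of pixel centres along the axis."""
        dr, dc = self.direction_rc
        r0, c0 = self.centroid_rc
        return (np.asarray(rows) - r0) * dr + (np.asarray(cols) - c0) * dc

    def perp_coords(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr, dc = self.direction_rc
        r0, c0 = self.centroid_rc
        return -(np.asarray(rows) - r0) * dc + (np.asarray(cols) - c0) * dr


@dataclass(frozen=True)
class WindowMeasurement:
    window_index: int
    start_um: float
    end_um: float
    perimeter_um: float
    full_scales: int
    partial_scales: int

    @property
    def scale_count(self) -> float:
        return self.full_scales + 0.5 * self.partial_scales


@dataclass
class FibreMeasurement:
    """Per-fibre summary; window values are averaged over full windows."""

    id: str
    diameter_um: float
    diameter_cv_pct: float
    windows: list[WindowMeasurement] = field(default_factory=list)

    @property
    def total_perimeter_per_100um(self) -> float:
        if not self.windows:
            return float("nan")
        return float(np.mean([w.perimeter_um for w in self.windows]))

    @property
    def scales_per_100um(self) -> float:
        if not self.windows:
            return float("nan")
        # reported at the 0.5 granularity used when counting
        return round(float(np.mean([w.scale_count for w in self.windows])) * 2) / 2

    @property
    def spi(self) -> float:
        return compute_spi(self.total_perimeter_per_100um, self.diameter_um)

    @property
    def pattern(self) -> ScalePattern:
        return classify_pattern(self.diameter_um)


# ---------------------------------------------------------------------------
# fibre detection


def detect_fibre(
    image: FibreImage, n_chords: int = 50
) -> tuple[FibreAxis, np.ndarray, float, float]:
    """Locate the fibre band and measure its diameter.

    Returns ``(axis, mask, diameter_um, diameter_cv_pct)``.  The mask is the
    largest connected foreground component after Otsu thresholding (holes
    filled); the axis is the total-least-squares line through the mask pixel
    centroids; the diameter is the mean of ``n_chords`` chord lengths taken
    perpendicular to the axis at evenly spaced stations.
    """
    px = np.asarray(image.pixels, dtype=float)
    thr = threshold_otsu(px) if px.max() > px.min() else px.max()
    fg = px > thr
    if not fg.any():
        raise ValueError("no fibre: empty foreground after thresholding")
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = labels == biggest
    if mask.sum() < 0.01 * mask.size:
        raise ValueError("no fibre: largest component below 1% of frame")
    mask = ndi.binary_fill_holes(mask)

    edges_touched = sum(
        (mask[0, :].any(), mask[-1, :].any(), mask[:, 0].any(), mask[:, -1].any())
    )
    if edges_touched < 2:
        warnings.warn("fibre fragment: component touches fewer than 2 frame edges")

    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols]).astype(float)
    centroid = pts.mean(axis=0)
    # first principal direction = total-least-squares line
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    direction = vt[0]
    if direction[1] < 0:  # orient along +columns for reproducibility
        direction = -direction

    t = (pts - centroid) @ direction
    s = (pts - centroid) @ np.array([-direction[1], direction[0]])
    t_min, t_max = t.min(), t.max()
    axis = FibreAxis(
        centroid_rc=(float(centroid[0]), float(centroid[1])),
        direction_rc=(float(direction[0]), float(direction[1])),
        length_px=float(t_max - t_min + 1.0),
    )

    stations = np.linspace(t_min, t_max, n_chords)
    chords = []
    for ts in stations:
        sel = np.abs(t - ts) <= 0.5
        if not sel.any():
            continue
        chords.append((s[sel].max() - s[sel].min() + 1.0) * image.um_per_px)
    chords = np.asarray(chords)
    if chords.size == 0:
        raise ValueError("no fibre: could not take perpendicular chords")
    diameter = float(chords.mean())
    cv = float(100.0 * chords.std(ddof=0) / diameter) if diameter > 0 else 0.0
    return axis, mask, diameter, cv


# ---------------------------------------------------------------------------
# scale-boundary skeleton


def segment_scale_edges(
    image: FibreImage,
    mask: np.ndarray,
    smooth_sigma: float = 0.0,
    min_spur_px: int = 3,
) -> np.ndarray:
    """Extract a 1-px-wide skeleton of the bright scale boundaries in ``mask``.

    Boundary ridges are hysteresis-thresholded against the fibre-body grey
    level, thinned, and spurs shorter than ``min_spur_px`` pruned.  An empty
    skeleton is a valid result (a fibre with no resolvable boundaries).
    """
    px = np.asarray(image.pixels, dtype=float)
    if smooth_sigma > 0:
        px = gaussian(px, sigma=smooth_sigma, preserve_range=True)
    vals = px[mask]
    if vals.size == 0 or vals.max() - vals.min() < 1e-9:
        return np.zeros_like(mask, dtype=bool)
    high = threshold_otsu(vals)
    bright = vals > high
    # no distinct bright ridge class: all-body or nearly-all-body fibres
    frac = bright.mean()
    if frac == 0 or frac > 0.5:
        return np.zeros_like(mask, dtype=bool)
    low = 0.5 * (np.median(vals[~bright]) + high)
    ridge = apply_hysteresis_threshold(px, low, high) & mask
    skel = skeletonize(ridge)
    return _prune_spurs(skel, min_spur_px)


def _prune_spurs(skel: np.ndarray, min_len: int) -> np.ndarray:
    """Remove endpoint branches shorter than ``min_len`` px that hang off a
    junction; free-standing short components are kept (they may be real)."""
    if min_len <= 0 or not skel.any():
        return skel
    kernel = np.ones((3, 3), dtype=int)
    nbrs = ndi.convolve(skel.astype(int), kernel, mode="constant") - skel
    junctions = skel & (nbrs >= 3)
    if not junctions.any():
        return skel
    branches = skel & ~junctions
    labels, n = ndi.label(branches, structure=kernel)
    out = skel.copy()
    dil_j = ndi.binary_dilation(junctions, structure=kernel.astype(bool))
    endpoints = skel & (nbrs <= 1)
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < min_len and (comp & endpoints).any() and (comp & dil_j).any():
            out[comp] = False
    return out


# ---------------------------------------------------------------------------
# chain-code skeleton length


def skeleton_edges(skel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency edges of a binary skeleton as chain-code steps.

    Returns ``(midpoints, weights)`` where ``midpoints`` is an (n, 2) array of
    edge midpoints in (row, col) pixel coordinates and ``weights`` the step
    lengths in px: 1 per 4-connected step, √2 per diagonal step.  A diagonal
    step is skipped when the two pixels share a 4-connected skeleton
    neighbour (the pair of unit steps through it is already counted).
    """
    s = np.asarray(skel, dtype=bool)
    mids: list[np.ndarray] = []
    wts: list[np.ndarray] = []

    def _pairs(a_idx, b_idx, weight):
        if a_idx[0].size:
            mid = np.column_stack(
                [(a_idx[0] + b_idx[0]) / 2.0, (a_idx[1] + b_idx[1]) / 2.0]
            )
            mids.append(mid)
            wts.append(np.full(mid.shape[0], weight))

    # horizontal and vertical unit steps
    h = s[:, :-1] & s[:, 1:]
    r, c = np.nonzero(h)
    _pairs((r, c), (r, c + 1), 1.0)
    v = s[:-1, :] & s[1:, :]
    r, c = np.nonzero(v)
    _pairs((r, c), (r + 1, c), 1.0)
    # diagonal steps, excluding shortcut diagonals across a 4-connected corner
    d1 = s[:-1, :-1] & s[1:, 1:] & ~(s[:-1, 1:] | s[1:, :-1])
    r, c = np.nonzero(d1)
    _pairs((r, c), (r + 1, c + 1), SQRT2)
    d2 = s[:-1, 1:] & s[1:, :-1] & ~(s[:-1, :-1] | s[1:, 1:])
    r, c = np.nonzero(d2)
    _pairs((r, c + 1), (r + 1, c), SQRT2)

    if not mids:
        return np.empty((0, 2)), np.empty(0)
    return np.concatenate(mids), np.concatenate(wts)


def skeleton_length_px(skel: np.ndarray) -> float:
    """Total chain-code length of a skeleton, in pixels."""
    _, w = skeleton_edges(skel)
    return float(w.sum())


# ---------------------------------------------------------------------------
# windowed measurement


def measure_windows(
    skeleton: np.ndarray,
    axis: FibreAxis,
    mask: np.ndarray,
    um_per_px: float,
    window_um: float = 100.0,
) -> list[WindowMeasurement]:
    """Tile the fibre axis into full ``window_um`` windows and measure each.

    Per window: ``perimeter_um`` is the chain-code length of the skeleton
    edges whose midpoints fall inside the window; scale regions are the
    4-connected components of the mask minus the (1-px dilated) skeleton — a
    region entirely inside a window counts 1, a region cut by a window
    boundary or by the frame counts 0.5.  Incomplete trailing windows are
    discarded.
    """
    rows, cols = np.nonzero(mask)
    t_all = axis.axial_coords(rows, cols)
    t0, t1 = t_all.min(), t_all.max()
    extent_um = (t1 - t0 + 1.0) * um_per_px
    n_win = int(np.floor(extent_um / window_um + 1e-9))
    if n_win < 1:
        raise ValueError("fibre too short: axis shorter than one window")
    origin = t0 - 0.5  # window origin at the leading pixel edge

    def to_um(t_px: np.ndarray) -> np.ndarray:
        return (np.asarray(t_px) - origin) * um_per_px

    # perimeter per window from skeleton edge midpoints
    perim = np.zeros(n_win)
    mids, wts = skeleton_edges(skeleton)
    if mids.shape[0]:
        t_mid = to_um(axis.axial_coords(mids[:, 0], mids[:, 1]))
        idx = np.floor(t_mid / window_um).astype(int)
        ok = (idx >= 0) & (idx < n_win)
        np.add.at(perim, idx[ok], wts[ok] * um_per_px)

    # scale regions: components of mask minus thickened skeleton
    blocked = ndi.binary_dilation(skeleton, structure=np.ones((3, 3), dtype=bool))
    regions = mask & ~blocked
    labels, n_reg = ndi.label(regions, structure=ndi.generate_binary_structure(2, 1))
    full = np.zeros(n_win, dtype=int)
    partial = np.zeros(n_win, dtype=int)
    if n_reg:
        rr, cc = np.nonzero(labels)
        t_um = to_um(axis.axial_coords(rr, cc))
        lab = labels[rr, cc]
        rmin = ndi.minimum(t_um, labels=lab, index=np.arange(1, n_reg + 1))
        rmax = ndi.maximum(t_um, labels=lab, index=np.arange(1, n_reg + 1))
        fibre_lo, fibre_hi = to_um(np.array([t0]))[0], to_um(np.array([t1]))[0]
        tol = 1.5 * um_per_px
        at_frame = (rmin <= fibre_lo + tol) | (rmax >= fibre_hi - tol)
        for w in range(n_win):
            a, b = w * window_um, (w + 1) * window_um
            overlaps = (rmin < b) & (rmax >= a)
            inside = overlaps & ~at_frame & (rmin >= a - tol) & (rmax < b + tol)
            # strict interior containment: also clear of the window boundary
            inside &= (rmin > a + tol) & (rmax < b - tol)
            full[w] = int(inside.sum())
            partial[w] = int((overlaps & ~inside).sum())

    return [
        WindowMeasurement(
            window_index=w,
            start_um=float(w * window_um),
            end_um=float((w + 1) * window_um),
            perimeter_um=float(perim[w]),
            full_scales=int(full[w]),
            partial_scales=int(partial[w]),
        )
        for w in range(n_win)
    ]


# ---------------------------------------------------------------------------
# derived scalar parameters


def compute_spi(perimeter_per_100um: float, diameter_um: float) -> float:
    """Scale perimeter index: boundary perimeter per 100 µm over diameter."""
    if not diameter_um > 0:
        raise ValueError("diameter must be positive")
    if perimeter_per_100um < 0:
        raise ValueError("perimeter must be non-negative")
    return perimeter_per_100um / diameter_um


def classify_pattern(diameter_um: float) -> ScalePattern:
    """Diameter-based pattern class: <25 µm coronal, 25–50 µm
    coronal-reticulate (boundaries inclusive), >50 µm reticulate."""
    if not diameter_um > 0:
        raise ValueError("diameter must be positive")
    if diameter_um < 25.0:
        return ScalePattern.CORONAL
    if diameter_um <= 50.0:
        return ScalePattern.CORONAL_RETICULATE
    return ScalePattern.RETICULATE


def measure_fibre(
    image: FibreImage,
    window_um: float = 100.0,
    smooth_sigma: float = 0.0,
) -> FibreMeasurement:
    """End-to-end measurement of one fibre image."""
    axis, mask, diameter, cv = detect_fibre(image)
    skel = segment_scale_edges(image, mask, smooth_sigma=smooth_sigma)
    windows = measure_windows(skel, axis, mask, image.um_per_px, window_um)
    return FibreMeasurement(
        id=image.id, diameter_um=diameter, diameter_cv_pct=cv, windows=windows
    )
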