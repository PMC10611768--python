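"""Dye-bath uptake kinetics and apparent diffusion-coefficient estimation.

The apparent diffusion coefficient D is obtained from the early-phase slope
of relative uptake Mt/Me against sqrt(time): for a finite bath the early
uptake follows Mt/Me = 4*sqrt(D*t/(pi*r^2)), so a through-origin
least-squares slope k on sqrt(seconds) gives D = k^2 * pi * r^2 / 16.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DyebathRecord",
    "UptakeSeries",
    "DiffusionFit",
    "absorbance_to_concentration",
    "compute_Mt",
    "estimate_Me",
    "fit_hill",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class DyebathRecord:
    """Dye-bath metadata: initial concentration (mg/ml), bath volume (ml),
    fibre mass (g), fibre radius (cm) and the absorbance calibration
    ``(slope, intercept)`` mapping concentration to absorbance.  The
    calibration may be omitted (None) when uptake is recorded directly as
    concentration or Mt."""

    C0: float
    V: float
    W: float
    radius_cm: float
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("C0", "V", "W", "radius_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.calibration is not None and not self.calibration[0] > 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class UptakeSeries:
    """One replicate's uptake record: Mt (mg dye per g fibre) against time."""

    bath: DyebathRecord
    times_min: tuple[float, ...]
    mt_mg_g: tuple[float, ...]
    replicate_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        m = np.asarray(self.mt_mg_g, dtype=float)
        if t.size == 0 or t.size != m.size:
            raise ValueError("times and uptake values must be non-empty and aligned")
        if (t < 0).any():
            raise ValueError("times must be non-negative")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times_min, dtype=float)

    @property
    def mt(self) -> np.ndarray:
        return np.asarray(self.mt_mg_g, dtype=float)


@dataclass(frozen=True)
class DiffusionFit:
    """Early-phase through-origin fit of Mt/Me on sqrt(t seconds)."""

    Me: float
    slope_k: float  # per sqrt(second)
    D: float  # cm^2 s^-1
    n_points_used: int
    fit_window: float  # Mt/Me cutoff
    r_squared: float
    flags: tuple[str, ...] = ()
    stderr_D: float | None = None


def absorbance_to_concentration(
    A, calibration: tuple[float, float]
) -> np.ndarray | float:
    """Invert a linear Beer–Lambert calibration: (A - intercept)/slope,
    clipped at zero."""
    slope, intercept = calibration
    if not slope > 0:
        raise ValueError("calibration slope must be positive")
    c = (np.asarray(A, dtype=float) - intercept) / slope
    c = np.clip(c, 0.0, None)
    return float(c) if np.ndim(A) == 0 else c


def compute_Mt(C0: float, Ce, V: float, W: float):
    """Dye adsorbed per gram of fibre: (C0 - Ce) * V / W."""
    if not W > 0:
        raise ValueError("fibre mass W must be positive")
    if not (C0 > 0 and V > 0):
        raise ValueError("C0 and V must be positive")
    ce = np.asarray(Ce, dtype=float)
    if (ce > C0).any():
        warnings.warn("residual concentration above C0; clipping uptake at 0")
        ce = np.minimum(ce, C0)
    mt = (C0 - ce) * V / W
    return float(mt) if np.ndim(Ce) == 0 else mt


def estimate_Me(series: UptakeSeries, method="plateau") -> float:
    """Equilibrium uptake estimate.

    ``method='plateau'`` returns the mean of the final two Mt values (the
    points at t >= 180 min when the series extends that far); a numeric
    ``method`` is taken as a user-supplied Me.  Warns when the tail is still
    rising ('no plateau').
    """
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        if not method > 0:
            raise ValueError("user-supplied Me must be positive")
        return float(method)
    if method != "plateau":
        raise ValueError(f"unknown Me method {method!r}")
    mt = series.mt
    if mt.size < 2:
        raise ValueError("need at least 2 points to estimate Me")
    me = float(mt[-2:].mean())
    if me > 0 and (mt[-1] - mt[-2]) > 0.02 * me:
        warnings.warn("no plateau: series still rising at the last time point")
    return me


def fit_hill(
    series: UptakeSeries,
    Me: float | None = None,
    radius_cm: float | None = None,
    cutoff: float = 0.5,
) -> DiffusionFit:
    """Estimate D from the early-phase slope of Mt/Me against sqrt(t).

    Only points with Mt/Me <= ``cutoff`` enter the through-origin
    least-squares fit; at least 3 such points are required.  The slope k (per
    sqrt-second) gives D = k^2 * pi * r^2 / 16.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    me = estimate_Me(series) if Me is None else float(Me)
    if not me > 0:
        raise ValueError("Me must be positive")
    r = series.bath.radius_cm if radius_cm is None else float(radius_cm)
    if not r > 0:
        raise ValueError("radius_cm must be positive")

    y = series.mt / me
    sel = y <= cutoff + 1e-12
    n = int(sel.sum())
    if n < 3:
        raise ValueError("insufficient early-phase data: fewer than 3 points below cutoff")
    x = np.sqrt(series.t[sel] * 60.0)
    ys = y[sel]

    flags: list[str] = []
    sxx = float(x @ x)
    k = float(x @ ys) / sxx if sxx > 0 else 0.0
    if k < 0:
        flags.append("negative slope")
        d = 0.0
    elif k == 0:
        flags.append("zero slope")
        d = 0.0
    else:
        d = k * k * np.pi * r * r / 16.0

    resid = ys - max(k, 0.0) * x
    ss_res = float(resid @ resid)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    if ss_tot < 1e-30:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return DiffusionFit(
        Me=me,
        slope_k=k,
        D=float(d),
        n_points_used=n,
        fit_window=cutoff,
        r_squared=r2,
        flags=tuple(flags),
    )


def aggregate_replicates(fits: list[DiffusionFit]) -> tuple[float, float]:
    """Mean and standard error of the mean of D across replicate fits.

    A single fit yields stderr 0 (there is no replication to average over).
    """
    if not fits:
        raise ValueError("need at least one fit")
    d = np.asarray([f.D for f in fits], dtype=float)
    if d.size == 1:
        return float(d[0]), 0.0
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(d.size))


def with_replicate_stderr(fit: DiffusionFit, stderr: float) -> DiffusionFit:
    return replace(fit, stderr_D=stderr)
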