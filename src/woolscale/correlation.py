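"""Morphology–diameter and diffusion–morphology correlation models.

The perimeter-versus-diameter relation is a quadratic through the origin,
y = a*x + b*x**2 (a fibre of zero diameter has zero scale perimeter); the
scale-count curve uses the same basis.  Breed-level diffusion coefficients
are related to morphology by ordinary least-squares lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .morphometry import FibreMeasurement, ScalePattern, classify_pattern, compute_spi

__all__ = [
    "CorrelationModel",
    "SpiBand",
    "SpiBands",
    "BandCheck",
    "LinearRelation",
    "ValidationReport",
    "fit_perimeter_model",
    "predict_perimeter",
    "spi_band_check",
    "fit_linear_relation",
    "validate_new_breed",
]


@dataclass(frozen=True)
class CorrelationModel:
    """No-intercept quadratic y = a*x + b*x**2.

    ``r_squared`` uses the centered total sum of squares; the uncentered
    variant is kept alongside because conventions for through-origin fits
    differ.
    """

    a: float
    b: float
    r_squared: float
    n: int
    response: str = "perimeter"
    r_squared_uncentered: float = float("nan")
    x_max: float = float("nan")

    @property
    def vertex(self) -> float:
        """Diameter at which the fitted curve turns over (inf if b >= 0)."""
        return self.a / (2.0 * abs(self.b)) if self.b < 0 else float("inf")


@dataclass(frozen=True)
class SpiBand:
    name: str
    d_lo: float
    d_hi: float  # inclusive upper diameter edge; +inf for the coarsest band
    spi_lo: float
    spi_hi: float


@dataclass(frozen=True)
class SpiBands:
    """Diameter-banded SPI reference ranges (fine / medium / coarse)."""

    fine: SpiBand = SpiBand("fine", 19.0, 30.0, 14.0, 20.0)
    medium: SpiBand = SpiBand("medium", 30.0, 65.0, 11.0, 15.0)
    coarse: SpiBand = SpiBand("coarse", 65.0, float("inf"), 6.0, 11.0)

    def __post_init__(self) -> None:
        bands = [self.fine, self.medium, self.coarse]
        for lo, hi in zip(bands, bands[1:]):
            if lo.d_hi > hi.d_lo:
                raise ValueError("diameter bands must be ordered and non-overlapping")

    def assign(self, diameter_um: float) -> SpiBand | None:
        if not diameter_um > 0:
            raise ValueError("diameter must be positive")
        if diameter_um < self.fine.d_lo:
            return None
        if diameter_um < self.fine.d_hi:
            return self.fine
        if diameter_um <= self.medium.d_hi:
            return self.medium
        return self.coarse


@dataclass(frozen=True)
class BandCheck:
    band: str
    in_range: bool | None


@dataclass(frozen=True)
class LinearRelation:
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class ValidationReport:
    diameter_um: float
    measured_perimeter: float
    predicted_perimeter: float
    residual: float
    spi: float
    band: str
    spi_in_range: bool | None
    expected_pattern: str
    observed_pattern: str
    pattern_matches: bool

    def to_dict(self) -> dict:
        return asdict(self)


def fit_perimeter_model(x, y, response: str = "perimeter") -> CorrelationModel:
    """Least squares over the no-intercept basis {x, x**2}.

    Requires >= 3 points with at least two distinct positive x.  The vertex
    of the fitted parabola should exceed the largest fitted diameter when
    b < 0 (the relation is monotone over the data range); a violation is
    reported as a warning, not an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D and aligned")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if (x <= 0).any():
        raise ValueError("diameters must be positive")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all x identical")
    design = np.column_stack([x, x * x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2:
        raise ValueError("degenerate design: collinear basis")
    a, b = (float(c) for c in coef)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_tot_unc = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-30 else 0.0)
    r2u = 1.0 - ss_res / ss_tot_unc if ss_tot_unc > 0 else 1.0
    model = CorrelationModel(
        a=a,
        b=b,
        r_squared=r2,
        n=int(x.size),
        response=response,
        r_squared_uncentered=r2u,
        x_max=float(x.max()),
    )
    if b < 0 and model.vertex <= model.x_max:
        warnings.warn(
            "fitted curve turns over inside the data range "
            f"(vertex {model.vertex:.1f} um <= max diameter {model.x_max:.1f} um)"
        )
    return model


def predict_perimeter(model: CorrelationModel, x: float) -> float:
    """Evaluate a*x + b*x**2; warns beyond the monotone range."""
    if not x > 0:
        raise ValueError("diameter must be positive")
    if x > model.vertex:
        warnings.warn(
            f"diameter {x:g} um beyond the model vertex {model.vertex:.1f} um; "
            "prediction is extrapolated past the turnover"
        )
    return model.a * x + model.b * x * x


def spi_band_check(
    diameter_um: float, spi: float, bands: SpiBands | None = None
) -> BandCheck:
    """Assign the diameter band and flag whether the SPI lies inside that
    band's inclusive range.  Diameters below the finest band are
    'unclassified'."""
    bands = bands or SpiBands()
    band = bands.assign(diameter_um)
    if band is None:
        return BandCheck(band="unclassified", in_range=None)
    return BandCheck(band=band.name, in_range=bool(band.spi_lo <= spi <= band.spi_hi))


def fit_linear_relation(points, predictor: str = "mean_diameter") -> LinearRelation:
    """Ordinary least-squares line through breed-level (predictor, D) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (predictor, D) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("identical predictor values: slope undefined")
    res = stats.linregress(x, y)
    return LinearRelation(
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


def validate_new_breed(
    measurement: FibreMeasurement,
    model: CorrelationModel,
    bands: SpiBands | None = None,
    observed_pattern: ScalePattern | None = None,
) -> ValidationReport:
    """Compare a newly measured fibre against the fitted framework: perimeter
    residual, SPI band membership and expected scale pattern."""
    d = measurement.diameter_um
    measured = measurement.total_perimeter_per_100um
    predicted = predict_perimeter(model, d)
    spi = compute_spi(measured, d)
    check = spi_band_check(d, spi, bands)
    expected = classify_pattern(d)
    observed = observed_pattern if observed_pattern is not None else measurement.pattern
    return ValidationReport(
        diameter_um=d,
        measured_perimeter=measured,
        predicted_perimeter=predicted,
        residual=measured - predicted,
        spi=spi,
        band=check.band,
        spi_in_range=check.in_range,
        expected_pattern=expected.value,
        observed_pattern=observed.value,
        pattern_matches=observed is expected,
    )
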