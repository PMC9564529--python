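"""Objective functions and forecasting for the human-needs scenarios.

Three linear objectives map a six-class land-use area vector x (km²) onto the
three levels of human need:

* **security** — ecological-footprint supply, ``f1 = Σ c_j x_j`` with
  published coefficients (0.02, 0.08, 0.45, 0.16, 0, 0);
* **spiritual** — green-equivalent share, ``f2 = (0.33x₁ + x₂ + 0.34x₃ +
  0.83x₄)/S``, the regional forest-equivalent greenness as a fraction of the
  total area S;
* **material** — economic benefit, ``f3 = Σ E_j x_j`` in RMB with per-km²
  benefit coefficients estimated by grey forecasting of yearbook series.

The module also implements the two forecasting procedures the scenarios rest
on: the single-variable grey model GM(1,1) (exact on exponential trends) and
the per-class ordinary-least-squares linear projection with proportional
closure to the fixed regional total (the no-intervention baseline).

Units: areas are km² throughout; footprint quantities are hm²
(1 km² = 100 hm²) and converted only at the constraint boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape_core import AreaVector

#: regional total land area, km²
REGION_TOTAL_KM2 = 33_481.23


@dataclass
class ObjectiveCoefficients:
    """Coefficients of the three scenario objectives (configurable).

    Defaults are the published values; they are taken as configuration, not
    re-derived from raw consumption tables.
    """

    security: np.ndarray = field(
        default_factory=lambda: np.array([0.02, 0.08, 0.45, 0.16, 0.0, 0.0])
    )
    #: green equivalents g₁..g₇ (g₅=g₆=g₇=0: built and unused land carry none)
    spiritual_g: np.ndarray = field(
        default_factory=lambda: np.array([0.33, 1.0, 0.34, 0.83, 0.0, 0.0, 0.0])
    )
    #: per-unit-area economic benefit, RMB per km²
    material_E: np.ndarray = field(
        default_factory=lambda: np.array(
            [362.33, 13.56, 168.47, 235.78, 45_783.88, 67_582.55]
        )
    )
    region_total_S: float = REGION_TOTAL_KM2

    def __post_init__(self) -> None:
        self.security = np.asarray(self.security, float)
        self.spiritual_g = np.asarray(self.spiritual_g, float)
        self.material_E = np.asarray(self.material_E, float)
        if (self.security < 0).any() or (self.spiritual_g < 0).any() or (
            self.material_E < 0
        ).any():
            raise ValueError("objective coefficients must be non-negative")
        if self.spiritual_g[4:].any():
            raise ValueError("green equivalents g5..g7 must be zero")


@dataclass
class FootprintResult:
    ef_per_capita: float  # hm² per person
    population: float

    @property
    def EF_total(self) -> float:
        """Total ecological footprint, hm²."""
        return self.population * self.ef_per_capita


def per_capita_footprint(table: pd.DataFrame) -> float:
    """Per-capita ecological footprint ef = Σ_j Σ_i r_j · c_i / p_i (hm²·cap⁻¹).

    ``table`` rows are consumption items with per-capita consumption ``c``
    (kg·cap⁻¹), national mean productivity ``p`` (kg·hm⁻²) and land-type
    equilibrium factor ``r``.
    """
    p = table["productivity_kg_per_hm2"].to_numpy(float)
    if (p <= 0).any():
        raise ValueError("productivity must be positive")
    c = table["consumption_kg_per_cap"].to_numpy(float)
    r = table["equilibrium_factor"].to_numpy(float)
    return float(np.sum(r * c / p))


def total_footprint(ef: float, population: float) -> float:
    """Total footprint EF = N × ef (hm²)."""
    if ef < 0 or population < 0:
        raise ValueError("ef and population must be non-negative")
    return float(population * ef)


def security_objective(x: AreaVector, coeffs: ObjectiveCoefficients | None = None) -> float:
    """f1(x): footprint-supply objective, Σ c_j x_j."""
    coeffs = coeffs or ObjectiveCoefficients()
    return float(coeffs.security @ x.area_km2)


def spiritual_objective(x: AreaVector, coeffs: ObjectiveCoefficients | None = None) -> float:
    """f2(x): green-equivalent share Σ g_j x_j / S, a dimensionless fraction."""
    coeffs = coeffs or ObjectiveCoefficients()
    if coeffs.region_total_S <= 0:
        raise ValueError("region total S must be positive")
    return float(coeffs.spiritual_g[:6] @ x.area_km2 / coeffs.region_total_S)


def material_objective(x: AreaVector, coeffs: ObjectiveCoefficients | None = None) -> float:
    """f3(x): economic benefit Σ E_j x_j (RMB)."""
    coeffs = coeffs or ObjectiveCoefficients()
    return float(coeffs.material_E @ x.area_km2)


# ---------------------------------------------------------------------------
# grey forecasting GM(1,1)
# ---------------------------------------------------------------------------

@dataclass
class GreyModel:
    """Fitted GM(1,1): development coefficient a, grey input b, first value."""

    a: float
    b: float
    x0_first: float
    n_obs: int


def gm11_fit(series: np.ndarray) -> GreyModel:
    """Fit a GM(1,1) grey model to a positive series of length >= 4.

    The observed series x⁰ is accumulated once to x¹; background values
    z(k) = ½(x¹(k) + x¹(k−1)) enter the least-squares problem
    x⁰(k) + a·z(k) = b, solved for (a, b). Exact on exponential series.
    """
    x0 = np.asarray(series, float)
    if x0.ndim != 1 or len(x0) < 4:
        raise ValueError("need a 1-D series of at least 4 observations")
    if (x0 <= 0).any():
        raise ValueError("GM(1,1) requires strictly positive observations")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z, np.ones(len(z))])
    y = x0[1:]
    (a, b), *_ = np.linalg.lstsq(B, y, rcond=None)
    return GreyModel(a=float(a), b=float(b), x0_first=float(x0[0]), n_obs=len(x0))


def _response(model: GreyModel, k: np.ndarray) -> np.ndarray:
    """Exact solution of the fitted grey difference equation at steps k >= 2.

    The fitted relation x⁰(k) + a·z(k) = b is a linear recurrence on the
    accumulated series with ratio r = (1 − a/2)/(1 + a/2); solving it
    directly (rather than through the continuous whitening equation's e^{−a})
    reproduces exponential inputs exactly, which is the property grey
    forecasting is used for here.
    """
    r = (1.0 - model.a / 2.0) / (1.0 + model.a / 2.0)
    amp = (model.x0_first - model.b / model.a) * (1.0 - 1.0 / r)
    return amp * r ** (k - 1.0)


def gm11_forecast(model: GreyModel, horizon: int) -> np.ndarray:
    """Forecast ``horizon`` values after the fitted sample.

    x̂⁰(k) = (x⁰(1) − b/a)(1 − r⁻¹) r^{k−1} with r = (1 − a/2)/(1 + a/2);
    the a → 0 limit is the constant series b.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if horizon == 0:
        return np.empty(0)
    k = np.arange(model.n_obs + 1, model.n_obs + horizon + 1)
    if abs(model.a) < 1e-12:
        return np.full(horizon, model.b)
    return _response(model, k)


def gm11_fitted(model: GreyModel) -> np.ndarray:
    """In-sample reconstruction (first value reproduced exactly)."""
    n = model.n_obs
    if abs(model.a) < 1e-12:
        out = np.full(n, model.b)
    else:
        out = np.concatenate(
            [[model.x0_first], _response(model, np.arange(2, n + 1))]
        )
    out[0] = model.x0_first
    return out


# ---------------------------------------------------------------------------
# linear-development baseline
# ---------------------------------------------------------------------------

def linear_projection(
    area_series: pd.DataFrame,
    target_year: float,
    region_total: float = REGION_TOTAL_KM2,
) -> AreaVector | pd.Series:
    """Per-class OLS linear extrapolation with closure to the regional total.

    ``area_series``: index = observation years, one column per class (km²).
    Each class is fitted with an ordinary least-squares line and evaluated at
    ``target_year``; negative extrapolations are floored at zero and the
    vector is then rescaled proportionally so it sums to ``region_total``.

    Returns an :class:`AreaVector` for the canonical six classes, otherwise
    a :class:`pandas.Series` (handy for reduced toy problems).
    """
    years = np.asarray(area_series.index, float)
    if len(years) < 2:
        raise ValueError("need at least two time points")
    if np.ptp(years) == 0:
        raise ValueError("all observation years are equal")
    raw = []
    for col in area_series.columns:
        slope, intercept = np.polyfit(years, area_series[col].to_numpy(float), 1)
        raw.append(max(0.0, slope * target_year + intercept))
    raw_arr = np.asarray(raw)
    total = raw_arr.sum()
    if total == 0:
        raise ValueError("all projected areas are zero; cannot close to total")
    scaled = raw_arr * (region_total / total)
    if len(area_series.columns) == 6:
        return AreaVector(scaled, class_labels=tuple(area_series.columns))
    return pd.Series(scaled, index=area_series.columns)
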