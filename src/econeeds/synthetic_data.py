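"""Synthetic inputs for the whole pipeline.

Real studies of this kind consume decades of classified 30 m land-use rasters,
continuous driver surfaces (terrain, accessibility, population, GDP), a
statutory ecological red line and yearbook consumption/economic tables. None
of those are redistributable here, so this module generates structurally
equivalent stand-ins with *known* ground truth:

* two-epoch categorical landscapes whose class conversions follow a logistic
  model on the drivers, so driver-importance recovery can be scored against
  the truth;
* smooth driver surfaces grouped by the human-needs taxonomy
  (security / spiritual / material);
* a contiguous red-line mask anchored on forest and water patches;
* a consumption/productivity table for ecological-footprint accounting with
  the published equilibrium factors;
* short annual economic series with controlled exponential growth for grey
  forecasting.

Default class fractions mirror the study region's 2020 composition (forest
dominant at ~74%, grassland ~13%, arable ~12%, little water and built land).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape_core import (
    CLASS_LABELS,
    N_CLASSES,
    NEEDS_GROUPS,
    NODATA,
    DriverStack,
    LandUseGrid,
    RedLineMask,
)

#: published land-type equilibrium factors (arable, grass, forest, water)
EQUILIBRIUM_FACTORS: dict[str, float] = {
    "arable": 1.74,
    "grass": 0.44,
    "forest": 1.41,
    "water": 0.35,
}

#: 2020 composition of the study region, used as default class fractions
_DEFAULT_FRACTIONS = (0.117, 0.743, 0.125, 0.0093, 0.0041, 0.0016)

DRIVER_NAMES = ("dem", "slope", "dist_rail", "dist_road", "dist_river",
                "pop_density", "gdp")


def _default_driver_effects() -> np.ndarray:
    """Per-class logistic weights on drivers; one dominant driver per class.

    Row k = class k's weights over :data:`DRIVER_NAMES`. Each class leans
    3x on one driver so the true importance ranking is known.
    """
    n_d = len(DRIVER_NAMES)
    eff = np.ones((N_CLASSES, n_d))
    for k in range(N_CLASSES):
        eff[k, k % n_d] = 3.0
    return eff


@dataclass
class LandscapeParams:
    rows: int = 100
    cols: int = 100
    class_fractions: tuple[float, ...] = _DEFAULT_FRACTIONS
    driver_effects: np.ndarray = field(default_factory=_default_driver_effects)
    change_fraction: float = 0.1
    cell_area: float = 1.0
    smoothing: float = 6.0  # gaussian field correlation length, cells
    redline_coverage: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.class_fractions, float)
        if fr.shape != (N_CLASSES,) or abs(fr.sum() - 1) > 1e-6 or (fr < 0).any():
            raise ValueError("class_fractions must be 6 non-negative values summing to 1")
        if not 0 <= self.change_fraction <= 0.5:
            raise ValueError("change_fraction must be in [0, 0.5]")
        if self.rows * self.cols < N_CLASSES:
            raise ValueError("grid too small for 6 classes")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _categorical_map(rng: np.random.Generator, params: LandscapeParams) -> np.ndarray:
    """Clustered categorical map with the target class fractions.

    Each class owns a smoothed Gaussian score field; classes claim their cell
    quota from rarest to commonest by taking their highest-scoring unassigned
    cells, so every class forms patches around its field's maxima and the
    empirical fractions match the targets exactly (up to rounding).
    """
    shape = (params.rows, params.cols)
    n = params.rows * params.cols
    fields = np.stack([_smooth_field(rng, shape, params.smoothing).ravel()
                       for _ in range(N_CLASSES)])
    target = np.asarray(params.class_fractions, float)
    quota = np.rint(target * n).astype(int)
    quota[np.argmax(quota)] += n - quota.sum()
    codes = np.zeros(n, dtype=np.int32)
    unassigned = np.ones(n, dtype=bool)
    for k in np.argsort(quota):
        if quota[k] == 0:
            continue
        free = np.flatnonzero(unassigned)
        take = free[np.argsort(-fields[k, free], kind="stable")[: quota[k]]]
        codes[take] = k + 1
        unassigned[take] = False
    if unassigned.any():  # rounding leftovers go to the commonest class
        codes[unassigned] = int(np.argmax(quota)) + 1
    return codes.reshape(shape)


def _driver_surfaces(rng: np.random.Generator, params: LandscapeParams) -> dict[str, np.ndarray]:
    """Smooth driver surfaces scaled to [0, 1]; slope derived from dem."""
    shape = (params.rows, params.cols)
    surfaces: dict[str, np.ndarray] = {}
    for name in DRIVER_NAMES:
        if name == "slope":
            continue
        f = _smooth_field(rng, shape, params.smoothing)
        surfaces[name] = (f - f.min()) / (f.max() - f.min())
    gy, gx = np.gradient(surfaces["dem"])
    slope = np.hypot(gy, gx)
    rng_span = slope.max() - slope.min()
    surfaces["slope"] = (slope - slope.min()) / (rng_span if rng_span > 0 else 1.0)
    return surfaces


def _transition(
    rng: np.random.Generator,
    codes0: np.ndarray,
    drivers: dict[str, np.ndarray],
    params: LandscapeParams,
) -> np.ndarray:
    """Convert ``change_fraction`` of cells; target class ~ logistic(effects·x)."""
    n = codes0.size
    n_change = int(round(params.change_fraction * n))
    if n_change == 0:
        return codes0.copy()
    flat0 = codes0.ravel()
    idx = rng.choice(n, size=n_change, replace=False)
    x = np.column_stack([drivers[d].ravel() for d in DRIVER_NAMES])
    # standardized drivers: weights are effect sizes per driver s.d., so the
    # 3x dominant weight genuinely dominates the transition propensity
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    logits = x[idx] @ np.asarray(params.driver_effects, float).T
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    # a cell cannot "convert" to its current class
    probs[np.arange(n_change), flat0[idx] - 1] = 0.0
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n_change)
    new_cls = (u[:, None] < cum).argmax(axis=1) + 1
    flat1 = flat0.copy()
    flat1[idx] = new_cls
    return flat1.reshape(codes0.shape)


def _redline(codes: np.ndarray, coverage: float) -> RedLineMask:
    """Contiguous mask anchored on forest/water patches at ~``coverage``.

    The forest∪water union is dilated or eroded toward the coverage target,
    then reduced to its largest connected component.
    """
    base = (codes == 2) | (codes == 4)
    n = codes.size
    mask = base.copy()
    for _ in range(max(codes.shape)):
        frac = mask.sum() / n
        if abs(frac - coverage) < 0.02:
            break
        if frac < coverage:
            mask = ndimage.binary_dilation(mask)
        else:
            eroded = ndimage.binary_erosion(mask)
            if eroded.sum() == 0:
                break
            mask = eroded
    labels, n_lab = ndimage.label(mask)
    if n_lab > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_lab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return RedLineMask(mask)


def generate_landscape(
    params: LandscapeParams,
) -> tuple[LandUseGrid, LandUseGrid, DriverStack, RedLineMask]:
    """Generate a two-epoch landscape with known driver-driven transitions.

    Returns ``(t0, t1, drivers, redline)``. The probability that a changing
    cell converts to class k is a softmax-logistic function of
    ``driver_effects[k] · drivers``, so the true driver ranking per class is
    known by construction. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    codes0 = _categorical_map(rng, params)
    drivers = _driver_surfaces(rng, params)
    codes1 = _transition(rng, codes0, drivers, params)
    t0 = LandUseGrid(codes0, cell_area=params.cell_area, epoch="t0")
    t1 = LandUseGrid(codes1, cell_area=params.cell_area, epoch="t1")
    stack = DriverStack(drivers, needs_group=dict(NEEDS_GROUPS))
    redline = _redline(codes0, params.redline_coverage)
    return t0, t1, stack, redline


# ---------------------------------------------------------------------------
# tables and series
# ---------------------------------------------------------------------------

def generate_footprint_table(n_items_per_type: int = 5, seed: int = 0) -> pd.DataFrame:
    """Consumption/productivity table for footprint accounting.

    One row per consumption item: per-capita consumption ``c`` (kg·cap⁻¹),
    national mean productivity ``p`` (kg·hm⁻²) and the land-type equilibrium
    factor ``r`` (fixed at the published values: arable 1.74, grass 0.44,
    forest 1.41, water 0.35). ``c`` and ``p`` are log-normal draws in
    agronomically plausible ranges.
    """
    if n_items_per_type < 1:
        raise ValueError("n_items_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for land_type, r in EQUILIBRIUM_FACTORS.items():
        for i in range(n_items_per_type):
            c = float(rng.lognormal(mean=3.0, sigma=1.0))      # ~ tens of kg/cap
            p = float(rng.lognormal(mean=7.0, sigma=0.7))      # ~ thousands kg/hm²
            rows.append(
                {
                    "item": f"{land_type}_item_{i}",
                    "land_type": land_type,
                    "consumption_kg_per_cap": c,
                    "productivity_kg_per_hm2": p,
                    "equilibrium_factor": r,
                }
            )
    return pd.DataFrame(rows)


def generate_economic_series(
    n_years: int = 5,
    growth: float = 0.08,
    noise: float = 0.0,
    seed: int = 0,
    start_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Annual per-class economic value series with exponential trend.

    Each class series is ``v0 · (1+growth)^t`` with multiplicative log-normal
    noise of standard deviation ``noise``; columns are class labels, index is
    year step. With ``noise=0`` the series is the exact closed form, which a
    grey GM(1,1) model fits without error.
    """
    if n_years < 4:
        raise ValueError("n_years must be >= 4 for grey model fitting")
    rng = np.random.default_rng(seed)
    if start_values is None:
        start_values = {c: 100.0 for c in CLASS_LABELS}
    t = np.arange(n_years)
    data = {}
    for cls, v0 in start_values.items():
        series = v0 * (1.0 + growth) ** t
        if noise > 0:
            series = series * np.exp(rng.normal(0.0, noise, n_years))
        data[cls] = series
    return pd.DataFrame(data, index=pd.Index(t, name="year_step"))
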