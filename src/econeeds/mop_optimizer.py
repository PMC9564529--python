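"""Constrained linear programs for the land-use structure scenarios.

One LP per scenario over the six class areas x₁..x₆ (km²): maximize the
security, material or spiritual objective — or an ideal-point-normalized
weighted sum of all three for the comprehensive scenario — subject to the
regional planning constraint set (fixed total area, population capacity
bracket, arable and water floors, built-land bracket, per-capita footprint
bracket, non-negativity). The linear-development baseline is not an LP and is
produced by :func:`econeeds.needs_models.linear_projection`.

Every constraint can be disabled individually, and any area vector can be
audited against the full set, because published scenario solutions of this
kind do not always satisfy every printed bound (the audit reports signed
slack instead of guessing unprinted constraints).

Solving uses scipy's HiGHS backend with a fixed configuration, so repeated
runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .landscape_core import AreaVector
from .needs_models import (
    ObjectiveCoefficients,
    material_objective,
    security_objective,
    spiritual_objective,
)

SCENARIOS = ("security", "material", "spiritual", "comprehensive", "ld")

_ECO = np.array([1, 1, 1, 0, 0, 0], float)      # arable+forest+grass
_BUILT = np.array([0, 0, 0, 0, 1, 1], float)    # residential+industrial
_FOOT = np.array([1, 1, 1, 1, 0, 0], float)     # footprint land types


@dataclass
class ConstraintSet:
    """Planning constraint constants (km² and persons); all toggleable.

    Defaults transcribe the published planning bounds for the study region:
    population capacity 120 persons/km² on arable+forest+grass plus
    3000 persons/km² on built land, bracketed between the low- and
    high-development population projections.
    """

    total_area: float = 33_481.23
    pop_low: float = 4_523_100.0
    pop_high: float = 4_618_000.0
    pop_density_eco: float = 120.0
    pop_density_built: float = 3000.0
    arable_min: float = 3_919.27
    built_low: float = 136.49
    built_high: float = 143.27
    water_min: float = 311.17
    footprint_low: float = 32_527.23
    footprint_high: float = 32_787.82
    disabled: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for lo, hi in ((self.pop_low, self.pop_high),
                       (self.built_low, self.built_high),
                       (self.footprint_low, self.footprint_high)):
            if lo > hi:
                raise ValueError("constraint interval has low > high")

    def enabled(self, name: str) -> bool:
        return name not in self.disabled

    def disable(self, *names: str) -> "ConstraintSet":
        return replace(self, disabled=self.disabled | frozenset(names))

    def rows(self) -> list[dict]:
        """Constraint rows as (name, coefficients, low, high)."""
        pop = self.pop_density_eco * _ECO + self.pop_density_built * _BUILT
        e5 = np.eye(6)[4]
        rows = [
            dict(name="total_area", coef=np.ones(6),
                 low=self.total_area, high=self.total_area),
            dict(name="population", coef=pop,
                 low=self.pop_low, high=self.pop_high),
            dict(name="arable_min", coef=np.eye(6)[0],
                 low=self.arable_min, high=np.inf),
            dict(name="built_land", coef=e5,
                 low=self.built_low, high=self.built_high),
            dict(name="water_min", coef=np.eye(6)[3],
                 low=self.water_min, high=np.inf),
            dict(name="footprint", coef=_FOOT,
                 low=self.footprint_low, high=self.footprint_high),
        ]
        return [r for r in rows if self.enabled(r["name"])]


@dataclass
class LinearProgram:
    """Maximization LP: max c·x s.t. A_ub x <= b_ub, A_eq x = b_eq, x >= 0."""

    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    scenario: str = ""


@dataclass
class ScenarioDemand:
    """Solved per-class target areas for one scenario."""

    scenario: str
    areas: AreaVector | None
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded | error


def _objective_vector(
    scenario: str,
    coeffs: ObjectiveCoefficients,
    weights: tuple[float, float, float] | None = None,
    constraints: ConstraintSet | None = None,
) -> np.ndarray:
    if scenario == "security":
        return coeffs.security.copy()
    if scenario == "material":
        return coeffs.material_E.copy()
    if scenario == "spiritual":
        return coeffs.spiritual_g[:6] / coeffs.region_total_S
    if scenario == "comprehensive":
        return scalarize_comprehensive(coeffs, constraints or ConstraintSet(),
                                       weights or (1 / 3, 1 / 3, 1 / 3))
    raise ValueError(f"unknown scenario {scenario!r}")


def build_lp(
    scenario: str,
    coeffs: ObjectiveCoefficients | None = None,
    constraints: ConstraintSet | None = None,
    weights: tuple[float, float, float] | None = None,
) -> LinearProgram:
    """Assemble the LP for one scenario.

    ``scenario`` is one of security/material/spiritual/comprehensive; the
    linear-development baseline (``ld``) is a projection, not an LP.
    """
    if scenario == "ld":
        raise ValueError("the LD baseline is a linear projection, not an LP")
    coeffs = coeffs or ObjectiveCoefficients()
    constraints = constraints or ConstraintSet()
    c = _objective_vector(scenario, coeffs, weights, constraints)
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for row in constraints.rows():
        coef, lo, hi = row["coef"], row["low"], row["high"]
        if lo == hi:
            A_eq.append(coef)
            b_eq.append(lo)
            continue
        if np.isfinite(hi):
            A_ub.append(coef)
            b_ub.append(hi)
        if np.isfinite(lo):
            A_ub.append(-coef)
            b_ub.append(-lo)
    to2d = lambda rows: np.asarray(rows, float).reshape(len(rows), 6)
    return LinearProgram(
        c=c, A_ub=to2d(A_ub), b_ub=np.asarray(b_ub, float),
        A_eq=to2d(A_eq), b_eq=np.asarray(b_eq, float), scenario=scenario,
    )


def solve_lp(lp: LinearProgram) -> ScenarioDemand:
    """Solve a maximization LP with the deterministic HiGHS dual simplex."""
    res = linprog(
        -lp.c,
        A_ub=lp.A_ub if lp.A_ub.size else None,
        b_ub=lp.b_ub if lp.b_ub.size else None,
        A_eq=lp.A_eq if lp.A_eq.size else None,
        b_eq=lp.b_eq if lp.b_eq.size else None,
        bounds=[(0, None)] * 6,
        method="highs-ds",
    )
    status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")
    if status != "optimal":
        return ScenarioDemand(lp.scenario, None, None, status)
    return ScenarioDemand(
        lp.scenario,
        AreaVector(np.maximum(res.x, 0.0)),
        float(lp.c @ res.x),
        "optimal",
    )


def scalarize_comprehensive(
    coeffs: ObjectiveCoefficients,
    constraints: ConstraintSet,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> np.ndarray:
    """Ideal-point-normalized weighted-sum objective for the joint scenario.

    Each single objective is first maximized alone to obtain its ideal value
    f_m*; the combined objective is Σ w_m f_m(x)/f_m*, which is again linear.
    """
    if abs(sum(weights) - 1) > 1e-9 or min(weights) < 0:
        raise ValueError("weights must be a 3-simplex vector")
    combined = np.zeros(6)
    for w, scen in zip(weights, ("security", "spiritual", "material")):
        if w == 0:
            continue
        sol = solve_lp(build_lp(scen, coeffs, constraints))
        if sol.status != "optimal" or sol.objective_value is None or sol.objective_value <= 0:
            raise ValueError(
                f"ideal value for {scen} unavailable (status {sol.status})"
            )
        combined += w * _objective_vector(scen, coeffs) / sol.objective_value
    return combined


def solve_scenario(
    scenario: str,
    coeffs: ObjectiveCoefficients | None = None,
    constraints: ConstraintSet | None = None,
    weights: tuple[float, float, float] | None = None,
) -> ScenarioDemand:
    """Convenience: build and solve one scenario LP."""
    return solve_lp(build_lp(scenario, coeffs, constraints, weights))


def audit_constraints(x: AreaVector, constraints: ConstraintSet | None = None) -> pd.DataFrame:
    """Evaluate every constraint row on an area vector.

    Returns a DataFrame with columns ``constraint, lhs, low, high, satisfied,
    slack``; slack is the signed distance to the nearest violated bound
    (positive = inside the feasible interval). Satisfaction uses a relative
    tolerance of 1e−6 on the bound magnitude.
    """
    constraints = constraints or ConstraintSet()
    recs = []
    v = x.area_km2
    rows = constraints.rows() + [
        dict(name=f"nonneg_x{i + 1}", coef=np.eye(6)[i], low=0.0, high=np.inf)
        for i in range(6)
    ]
    for row in rows:
        lhs = float(row["coef"] @ v)
        lo, hi = row["low"], row["high"]
        tol = 1e-6 * max(abs(lo) if np.isfinite(lo) else 0.0,
                         abs(hi) if np.isfinite(hi) else 0.0, 1.0)
        slack = min(
            lhs - lo if np.isfinite(lo) else np.inf,
            hi - lhs if np.isfinite(hi) else np.inf,
        )
        recs.append(
            dict(constraint=row["name"], lhs=lhs, low=lo, high=hi,
                 satisfied=bool(slack >= -tol), slack=float(slack))
        )
    return pd.DataFrame(recs)


def objective_values(x: AreaVector, coeffs: ObjectiveCoefficients | None = None) -> dict[str, float]:
    """All three objective values on one area vector."""
    coeffs = coeffs or ObjectiveCoefficients()
    return {
        "security": security_objective(x, coeffs),
        "spiritual": spiritual_objective(x, coeffs),
        "material": material_objective(x, coeffs),
    }
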