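"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: areas by explicit
per-cell loops, LP optima by exhaustive vertex enumeration, footprint sums by
double loops.
"""

from itertools import combinations

import numpy as np


def tally_areas(codes: np.ndarray, cell_area: float, n_classes: int = 6,
                nodata: int = -1) -> np.ndarray:
    """Per-class areas by an explicit per-cell loop."""
    areas = np.zeros(n_classes)
    for row in codes:
        for v in row:
            if v != nodata:
                areas[v - 1] += cell_area
    return areas


def footprint_double_loop(table) -> float:
    """ef = sum over land types and items of r*c/p, written as the double loop."""
    total = 0.0
    for land_type in table["land_type"].unique():
        sub = table[table["land_type"] == land_type]
        for _, row in sub.iterrows():
            total += (
                row["equilibrium_factor"]
                * row["consumption_kg_per_cap"]
                / row["productivity_kg_per_hm2"]
            )
    return total


def vertex_enumeration_max(c, A_ub, b_ub, A_eq=None, b_eq=None, tol=1e-9):
    """Optimum of max c.x s.t. A_ub x <= b_ub, A_eq x = b_eq, x >= 0.

    Enumerates every basic solution (all choices of n active hyperplanes,
    equalities always active), keeps the feasible ones and returns the best
    objective value, or None if no feasible vertex exists.
    """
    c = np.asarray(c, float)
    n = len(c)
    A_ub = np.asarray(A_ub, float).reshape(-1, n)
    b_ub = np.asarray(b_ub, float)
    planes_A = [A_ub, -np.eye(n)]
    planes_b = [b_ub, np.zeros(n)]
    n_eq = 0
    if A_eq is not None and len(A_eq):
        A_eq = np.asarray(A_eq, float).reshape(-1, n)
        b_eq = np.asarray(b_eq, float)
        n_eq = len(b_eq)
        planes_A.insert(0, A_eq)
        planes_b.insert(0, b_eq)
    A = np.vstack(planes_A)
    b = np.concatenate(planes_b)
    m = len(b)
    free = range(n_eq, m)
    combos = np.array(
        [list(range(n_eq)) + list(cmb) for cmb in combinations(free, n - n_eq)]
    )
    mats = A[combos]                      # (n_combo, n, n)
    rhs = b[combos]
    dets = np.abs(np.linalg.det(mats))
    ok = dets > 1e-10
    if not ok.any():
        return None
    xs = np.linalg.solve(mats[ok], rhs[ok][..., None])[..., 0]
    feas_ub = (A_ub @ xs.T <= b_ub[:, None] + tol).all(axis=0)
    feas_nn = (xs >= -tol).all(axis=1)
    feas = feas_ub & feas_nn
    if n_eq:
        feas &= (np.abs(A_eq @ xs.T - b_eq[:, None]) <= tol).all(axis=0)
    if not feas.any():
        return None
    return float((xs[feas] @ c).max())


def random_bounded_lp(rng, n=6, n_extra=3):
    """Random bounded-feasible maximization LP with box + extra constraints.

    x = 0 is always feasible; upper box bounds keep it bounded. Total facet
    count is 6 nonneg + 6 box + n_extra <= 15.
    """
    c = rng.uniform(-1, 1, n)
    hi = rng.uniform(1, 10, n)
    A = [np.eye(n)]
    b = [hi]
    for _ in range(n_extra):
        coef = rng.uniform(0, 1, n)
        bound = rng.uniform(0.5, 1.0) * coef @ hi
        A.append(coef[None, :])
        b.append([bound])
    return c, np.vstack(A), np.concatenate(b)
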