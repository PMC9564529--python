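"""CA allocation with multi-type random patch seeds (CARS).

Spatially allocates a scenario's per-class area demands onto the landscape.
Each iteration combines, per candidate cell and class k,

* the random-forest growth probability P_k,
* the neighborhood effect Ω_k (share of k in the surrounding window),
* an adaptive demand coefficient D_k reacting to the gap between current
  area and demand,

into the overall probability ``OP = P·Ω·D``. Where a class has no
neighborhood presence (Ω = 0), random patch seeding applies instead with
probability given by the expansion coefficient: ``OP = P·r·μ·D`` for a
uniform draw r < P, with patch-generation threshold μ. A roulette wheel over
the class OPs nominates one target class per cell; nominations are accepted
against a competition threshold τ that starts at 1 and halves whenever an
iteration converts nothing, so the strongest conversions happen first.
Conversions only move cells from surplus classes to deficit classes, under a
from→to transition-rule matrix and a frozen-cell mask, so the total cell
count is conserved exactly at every step. Once τ has decayed away, any
residual deficit is filled deterministically by shedding the surplus cells
with the lowest retention probability (the paper-style description covers
growth only; shedding is this implementation's mechanism for demanded
shrinkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .landscape_core import N_CLASSES, AreaVector, LandUseGrid
from .leas import fit_all_classes

_TAU_FLOOR = 1e-9


def default_allowed() -> np.ndarray:
    """Default from→to matrix: ecological classes interconvert freely;
    built-up land (residential, industrial-mining-transport) neither converts
    away nor absorbs other classes — its area is fixed by construction."""
    allowed = np.ones((N_CLASSES, N_CLASSES), dtype=bool)
    allowed[4:, :] = False
    allowed[:, 4:] = False
    np.fill_diagonal(allowed, True)
    return allowed


@dataclass
class TransitionRules:
    allowed: np.ndarray = field(default_factory=default_allowed)
    frozen_mask: np.ndarray | None = None  # cells that never change

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if self.allowed.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("allowed must be 6x6")
        if not np.diag(self.allowed).all():
            raise ValueError("self-transitions must always be allowed")


@dataclass
class CarsParams:
    """Tunables of the allocation CA.

    ``patch_threshold`` μ (scalar or per-class) damps seeded patches;
    ``expansion_coefficient`` is the probability of attempting a random seed
    where Ω = 0; ``tau_decay`` is the multiplicative decrease of the
    competition threshold on stalled iterations; ``demand_tol_frac`` is the
    demand tolerance as a fraction of the total area.
    """

    patch_threshold: float | np.ndarray = 0.5
    expansion_coefficient: float = 0.1
    window: int = 3
    tau_decay: float = 0.5
    demand_tol_frac: float = 0.001
    max_iterations: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        mu = np.broadcast_to(np.asarray(self.patch_threshold, float), (N_CLASSES,))
        if ((mu < 0) | (mu > 1)).any():
            raise ValueError("patch_threshold must lie in [0, 1]")
        if not 0 <= self.expansion_coefficient <= 1:
            raise ValueError("expansion_coefficient must lie in [0, 1]")
        if not 0 < self.tau_decay < 1:
            raise ValueError("tau_decay must lie in (0, 1)")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")

    def mu(self, k: int) -> float:
        return float(np.broadcast_to(
            np.asarray(self.patch_threshold, float), (N_CLASSES,))[k - 1])


def neighborhood_effect(grid: LandUseGrid, k: int, window: int = 3) -> np.ndarray:
    """Ω_k: share of class k in the window around each cell, center excluded.

    Interior cells divide by window²−1; edge cells by the clipped window's
    in-bounds cell count minus one.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    is_k = (grid.codes == k).astype(float)
    size = (window, window)
    counts = ndimage.uniform_filter(is_k, size=size, mode="constant", cval=0.0)
    counts = counts * window * window - is_k
    in_bounds = ndimage.uniform_filter(
        np.ones_like(is_k), size=size, mode="constant", cval=0.0
    ) * window * window - 1.0
    return np.clip(counts, 0.0, None) / np.maximum(np.rint(in_bounds), 1.0)


def adaptive_coefficient(
    D_prev: float, demand_k: float, area_now: float, area_prev: float
) -> float:
    """Update the demand-driving coefficient D_k from the gap trajectory.

    The gap is G = demand − area. If |G| did not grow since the previous
    iteration (including G = 0), D is unchanged; if the gap grew and kept its
    sign, D is scaled by G_now/G_prev and clipped to [0.1, 10] so pressure
    rises on classes drifting away from their demand.
    """
    g_now = demand_k - area_now
    g_prev = demand_k - area_prev
    if abs(g_now) <= abs(g_prev) or g_prev == 0:
        return D_prev
    if g_now * g_prev > 0:
        return float(np.clip(D_prev * (g_now / g_prev), 0.1, 10.0))
    return D_prev


def overall_probability(P: np.ndarray, omega: np.ndarray, D_k: float) -> np.ndarray:
    """Neighborhood branch: OP = P · Ω · D."""
    return P * omega * D_k


def overall_probability_seed(
    P: np.ndarray, r: np.ndarray, mu_k: float, D_k: float
) -> np.ndarray:
    """Seeding branch (Ω = 0, r < P): OP = P · r · μ · D."""
    return P * r * mu_k * D_k


def _target_cells(demand: AreaVector, grid: LandUseGrid) -> np.ndarray:
    """Demanded cell counts per class, closed to the grid's valid cell total."""
    n_valid = int(grid.valid.sum())
    counts = np.rint(demand.area_km2 / grid.cell_area).astype(int)
    counts[np.argmax(counts)] += n_valid - counts.sum()
    if (counts < 0).any():
        raise ValueError("demand rounds to a negative cell count")
    return counts


def _check_reachable(
    target: np.ndarray, counts: np.ndarray, rules: TransitionRules, tol: int
) -> None:
    for k in range(N_CLASSES):
        others = np.delete(np.arange(N_CLASSES), k)
        if target[k] > counts[k] + tol and not rules.allowed[others, k].any():
            raise ValueError(
                f"demand requires growth of class {k + 1}, but no transition "
                f"into it is allowed"
            )
        if target[k] < counts[k] - tol and not rules.allowed[k, others].any():
            raise ValueError(
                f"demand requires shrinkage of class {k + 1}, but no "
                f"transition out of it is allowed"
            )


def allocate(
    t_base: LandUseGrid,
    probs: dict[int, np.ndarray],
    demand: AreaVector,
    rules: TransitionRules | None = None,
    params: CarsParams | None = None,
    full_output: bool = False,
):
    """Allocate per-class demands on the landscape; deterministic under seed.

    Returns the allocated :class:`LandUseGrid`, or ``(grid, diagnostics)``
    when ``full_output`` is set; diagnostics carry the per-iteration area
    log, τ trajectory and iteration count.
    """
    rules = rules or TransitionRules()
    params = params or CarsParams()
    rng = np.random.default_rng(params.seed)

    codes = t_base.codes.copy()
    valid = t_base.valid
    n_valid = int(valid.sum())
    total_km2 = n_valid * t_base.cell_area
    if abs(demand.total - total_km2) > max(0.5 * t_base.cell_area,
                                           params.demand_tol_frac * total_km2):
        raise ValueError(
            f"demand total {demand.total:.2f} km² != grid valid area "
            f"{total_km2:.2f} km²"
        )
    missing = [k for k in range(1, N_CLASSES + 1) if k not in probs]
    if missing:
        raise ValueError(f"missing probability surfaces for classes {missing}")

    target = _target_cells(demand, t_base)
    tol_cells = int(params.demand_tol_frac * total_km2 / t_base.cell_area)

    frozen = np.zeros(codes.shape, bool)
    if rules.frozen_mask is not None:
        frozen = np.asarray(rules.frozen_mask, bool)
        if frozen.shape != codes.shape:
            raise ValueError("frozen_mask shape mismatch")
    mutable = valid & ~frozen
    # cells whose current class allows no exit are effectively frozen
    no_exit = ~rules.allowed.copy()
    np.fill_diagonal(no_exit, False)

    def counts_now() -> np.ndarray:
        return np.bincount(codes[valid], minlength=N_CLASSES + 1)[1:]

    counts = counts_now()
    _check_reachable(target, counts, rules, tol_cells)

    P = {k: np.nan_to_num(probs[k], nan=0.0) for k in range(1, N_CLASSES + 1)}
    D = np.ones(N_CLASSES)
    tau = 1.0
    prev_counts = counts.copy()
    area_log: list[np.ndarray] = [counts.copy()]
    tau_log: list[float] = []
    stalled = False
    it = 0

    flat_codes = codes.ravel()
    flat_mutable = mutable.ravel()

    while it < params.max_iterations:
        counts = counts_now()
        need = target - counts
        # aim for the exact cell targets; settle for the tolerance only once
        # allocation has genuinely stalled (threshold exhausted, no changes)
        worst = np.abs(need).max()
        if worst == 0 or (worst <= tol_cells and stalled):
            break
        it += 1
        for k in range(N_CLASSES):
            D[k] = adaptive_coefficient(
                D[k],
                target[k] * t_base.cell_area,
                counts[k] * t_base.cell_area,
                prev_counts[k] * t_base.cell_area,
            )
        prev_counts = counts.copy()

        # conversions aim at the exact targets; the tolerance only decides
        # termination, otherwise per-class leftovers can deadlock a donor
        deficit = [k for k in range(1, N_CLASSES + 1) if need[k - 1] > 0]
        surplus = {k for k in range(1, N_CLASSES + 1) if need[k - 1] < 0}

        grid_now = LandUseGrid(codes, cell_area=t_base.cell_area)
        donor = flat_mutable & np.isin(flat_codes, sorted(surplus))

        # --- roulette phase -------------------------------------------------
        op_rows = []
        omegas = {}
        for k in deficit:
            omega = neighborhood_effect(grid_now, k, params.window).ravel()
            omegas[k] = omega
            p = P[k].ravel()
            op = overall_probability(p, omega, D[k - 1])
            zero_nb = omega == 0
            if params.expansion_coefficient > 0 and zero_nb.any():
                attempt = rng.random(p.shape) < params.expansion_coefficient
                r = rng.random(p.shape)
                seeded = zero_nb & attempt & (r < p)
                op = np.where(
                    seeded,
                    overall_probability_seed(p, r, params.mu(k), D[k - 1]),
                    op,
                )
            eligible = donor & rules.allowed[flat_codes - 1, k - 1]
            op_rows.append(np.where(eligible, op, 0.0))
        n_changed = 0
        if deficit:
            op_mat = np.vstack(op_rows)  # (n_deficit, n_cells)
            mass = op_mat.sum(axis=0)
            cand = np.flatnonzero(mass > 0)
            if cand.size:
                u = rng.random(cand.size) * mass[cand]
                cum = np.cumsum(op_mat[:, cand], axis=0)
                choice = (u < cum).argmax(axis=0)  # ties -> lowest class code
                op_win = op_mat[choice, cand]
                accept = op_win >= tau
                cells = cand[accept]
                wins = choice[accept]
                op_acc = op_win[accept]
                order = np.lexsort((cells, -op_acc))  # OP desc, cell idx tie-break
                need_w = need.copy()
                for pos in order:
                    cell = cells[pos]
                    k = deficit[wins[pos]]
                    c = flat_codes[cell]
                    if need_w[k - 1] > 0 and need_w[c - 1] < 0:
                        flat_codes[cell] = k
                        need_w[k - 1] -= 1
                        need_w[c - 1] += 1
                        n_changed += 1

        if n_changed == 0:
            tau *= params.tau_decay

        # --- deterministic residual fill ------------------------------------
        # Once the competition threshold has decayed away, remaining deficits
        # are filled by shedding surplus cells with the lowest retention OP.
        if tau < _TAU_FLOOR:
            counts_live = counts_now()
            for k in sorted(range(1, N_CLASSES + 1),
                            key=lambda kk: counts_live[kk - 1] - target[kk - 1]):
                if target[k - 1] - counts_live[k - 1] <= 0:
                    continue
                omega_k = omegas.get(k)
                if omega_k is None:
                    omega_k = neighborhood_effect(grid_now, k, params.window).ravel()
                donor_now = flat_mutable & rules.allowed[flat_codes - 1, k - 1]
                if params.expansion_coefficient == 0:
                    donor_now &= omega_k > 0  # growth only along existing patches
                cand = np.flatnonzero(donor_now)
                if cand.size == 0:
                    continue
                retention = np.zeros(cand.size)
                for c in np.unique(flat_codes[cand]):
                    sel = flat_codes[cand] == c
                    om_c = neighborhood_effect(grid_now, int(c), params.window).ravel()
                    retention[sel] = (P[int(c)].ravel() * om_c * D[c - 1])[cand[sel]]
                order = np.lexsort((cand, retention))  # lowest retention first
                for cell in cand[order]:
                    if counts_live[k - 1] >= target[k - 1]:
                        break
                    c = flat_codes[cell]
                    if counts_live[c - 1] - 1 < target[c - 1]:
                        continue  # donor class no longer in surplus
                    flat_codes[cell] = k
                    counts_live[k - 1] += 1
                    counts_live[c - 1] -= 1
                    n_changed += 1

        new_counts = counts_now()
        assert new_counts.sum() == n_valid, "cell count not conserved"
        area_log.append(new_counts.copy())
        stalled = n_changed == 0 and tau < _TAU_FLOOR
        tau_log.append(tau)

    counts = counts_now()
    need = target - counts
    if np.abs(need).max() > tol_cells:
        unmet = [k + 1 for k in range(N_CLASSES) if abs(need[k]) > tol_cells]
        raise RuntimeError(
            f"allocation did not converge for classes {unmet} after {it} iterations"
        )

    out = LandUseGrid(flat_codes.reshape(codes.shape), cell_area=t_base.cell_area,
                      epoch="allocated", class_labels=t_base.class_labels)
    if frozen.any():
        assert (out.codes[frozen] == t_base.codes[frozen]).all()
    if not full_output:
        return out
    diagnostics = {
        "iterations": it,
        "area_log_cells": np.asarray(area_log),
        "tau_log": tau_log,
        "final_counts": counts,
        "target_counts": target,
    }
    return out, diagnostics


def run_scenario(
    t0: LandUseGrid,
    t1: LandUseGrid,
    drivers,
    demand: AreaVector,
    rules: TransitionRules | None = None,
    params: CarsParams | None = None,
    n_per_class: int = 5000,
    M: int = 50,
):
    """LEAS fit on t0→t1 followed by CA allocation of ``demand`` from t1.

    Returns ``(grid, diagnostics)``; diagnostics include the final area
    vector, iteration count and kappa agreement with the base epoch.
    """
    from .landscape_core import class_areas, kappa_agreement

    params = params or CarsParams()
    probs = fit_all_classes(t0, t1, drivers, n_per_class=n_per_class, M=M,
                            seed=params.seed)
    out, diag = allocate(t1, probs, demand, rules, params, full_output=True)
    diag["final_areas"] = class_areas(out)
    diag["kappa_vs_base"] = kappa_agreement(out, t1)
    return out, diag
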