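"""Land Expansion Analysis Strategy (LEAS).

Between two epochs, each class k has an *expansion set*: cells that were some
other class at t0 and are class k at t1. A per-class random-forest classifier
is trained on driver values at expanded vs non-expanded cells; the growth
probability of class k at cell i is the fraction of trees voting "expansion",

    P_k(i) = (1/M) Σ_n I[h_n(x_i) = 1],

which this module computes by explicit per-tree voting so the votes/M
semantics are exact regardless of leaf purity. Impurity-based driver
importances, normalized to sum one, summarize each driver's contribution to a
class's expansion; drivers serving two needs groups contribute half to each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .landscape_core import DriverStack, LandUseGrid

#: marker for cells ineligible as class-k training cells (already k at t0)
INELIGIBLE = -1


@dataclass
class ExpansionSamples:
    """Training table for one class: driver matrix X, labels y, cell indices."""

    X: np.ndarray
    y: np.ndarray
    cells: np.ndarray
    driver_names: list[str]
    k: int


@dataclass
class GrowthModel:
    """Per-class tree ensemble whose prediction is the vote ratio in [0, 1]."""

    k: int
    M: int
    forest: RandomForestClassifier
    driver_names: list[str]


def extract_expansion(t0: LandUseGrid, t1: LandUseGrid, k: int) -> np.ndarray:
    """Expansion map of class k: int8 matrix with

    * ``1``  — cell converted to k (t0 ≠ k, t1 = k),
    * ``0``  — eligible non-converted cell (t0 ≠ k, t1 ≠ k),
    * ``-1`` — ineligible (already k at t0, or nodata in either epoch):
      such cells are excluded from positives and from negative sampling.
    """
    if not t0.comparable(t1):
        raise ValueError("epoch grids are not comparable")
    valid = t0.valid & t1.valid
    out = np.full(t0.shape, INELIGIBLE, dtype=np.int8)
    eligible = valid & (t0.codes != k)
    out[eligible] = 0
    out[eligible & (t1.codes == k)] = 1
    return out


def sample_training(
    expansion: np.ndarray,
    drivers: DriverStack,
    n_per_class: int = 5000,
    strategy: str = "balanced",
    seed: int = 0,
    k: int | None = None,
) -> ExpansionSamples:
    """Draw training cells from an expansion map.

    ``balanced`` draws up to ``n_per_class`` positives and as many negatives
    (capped by availability, without replacement); ``uniform`` draws
    ``n_per_class`` cells uniformly from all eligible cells so the label
    frequency matches the map. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    flat = expansion.ravel()
    pos = np.flatnonzero(flat == 1)
    neg = np.flatnonzero(flat == 0)
    if len(pos) == 0:
        raise ValueError(f"no expansion cells for class {k if k is not None else '?'}")
    if strategy == "balanced":
        n_pos = min(n_per_class, len(pos))
        n_neg = min(n_pos, len(neg))
        cells = np.concatenate([
            rng.choice(pos, n_pos, replace=False),
            rng.choice(neg, n_neg, replace=False),
        ])
    elif strategy == "uniform":
        pool = np.concatenate([pos, neg])
        cells = rng.choice(pool, min(n_per_class, len(pool)), replace=False)
    else:
        raise ValueError(f"unknown sampling strategy {strategy!r}")
    cells.sort()
    names = drivers.names
    X = drivers.matrix(names)[cells]
    y = (flat[cells] == 1).astype(np.int8)
    return ExpansionSamples(X=X, y=y, cells=cells, driver_names=names,
                            k=-1 if k is None else k)


def fit_growth_model(samples: ExpansionSamples, M: int = 50, seed: int = 0) -> GrowthModel:
    """Fit the per-class ensemble of M classification trees (√d features/split)."""
    if M < 1:
        raise ValueError("need at least one tree")
    labels = np.unique(samples.y)
    if len(labels) < 2:
        raise ValueError("training samples contain a single label")
    forest = RandomForestClassifier(
        n_estimators=M, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(samples.X, samples.y)
    return GrowthModel(k=samples.k, M=M, forest=forest,
                       driver_names=list(samples.driver_names))


def _vote_ratio(model: GrowthModel, X: np.ndarray) -> np.ndarray:
    votes = np.zeros(len(X))
    for tree in model.forest.estimators_:
        votes += (tree.predict(X) == 1)
    return votes / model.M


def growth_probability(model: GrowthModel, drivers: DriverStack) -> np.ndarray:
    """Growth-probability surface P_k = votes/M per cell; NaN where drivers are not finite."""
    missing = [n for n in model.driver_names if n not in drivers.surfaces]
    if missing:
        raise ValueError(f"drivers missing from stack: {missing}")
    shape = drivers.shape
    X = drivers.matrix(model.driver_names)
    finite = np.isfinite(X).all(axis=1)
    p = np.full(X.shape[0], np.nan)
    if finite.any():
        p[finite] = _vote_ratio(model, X[finite])
    return p.reshape(shape)


def driver_importance(
    model: GrowthModel,
    needs_group: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Normalized per-driver importances and per-needs-group contributions.

    Impurity-based importances are normalized to sum one. A driver listed in
    g needs groups contributes ``importance/g`` to each, so group
    contributions also sum to one.
    """
    imp = np.asarray(model.forest.feature_importances_, float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    per_driver = pd.Series(imp, index=model.driver_names, name="importance")
    groups: dict[str, float] = {}
    if needs_group:
        for name, value in per_driver.items():
            gset = needs_group.get(name, ())
            for g in gset:
                groups[g] = groups.get(g, 0.0) + value / len(gset)
    return per_driver, pd.Series(groups, name="group_importance").sort_index()


def fit_all_classes(
    t0: LandUseGrid,
    t1: LandUseGrid,
    drivers: DriverStack,
    n_per_class: int = 5000,
    M: int = 50,
    seed: int = 0,
    fallback_probability: float = 0.5,
) -> dict[int, np.ndarray]:
    """Growth-probability surfaces for all six classes.

    Classes with no observed expansion between the epochs (typically built-up
    land under transfer restrictions) receive a flat uninformative surface at
    ``fallback_probability`` instead of failing.
    """
    surfaces: dict[int, np.ndarray] = {}
    for k in range(1, 7):
        expansion = extract_expansion(t0, t1, k)
        try:
            samples = sample_training(expansion, drivers, n_per_class,
                                      seed=seed + k, k=k)
            model = fit_growth_model(samples, M=M, seed=seed + k)
            surfaces[k] = growth_probability(model, drivers)
        except ValueError:
            surfaces[k] = np.full(t0.shape, fallback_probability)
    return surfaces
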