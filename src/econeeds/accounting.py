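"""Scenario change accounting, red-line intersection and pipeline driver.

The published scenario area table (six classes × 2020 status quo and five
scenario columns) ships as a versioned CSV fixture; every reported scenario
difference is *computed* from it through :func:`change_table`, never
hard-coded. Red-line reporting intersects scenario grids with the protection
mask and tabulates per-class areas and deltas against the masked baseline.
:func:`run_pipeline` chains the whole method on synthetic inputs:
generate landscape → demands (solver or fixture) → LEAS → CARS → accounting.
"""

from __future__ import annotations

import json
import os
from importlib import resources

import numpy as np
import pandas as pd

from . import cars as _cars
from . import landscape_core as lc
from . import mop_optimizer as mop
from . import synthetic_data as synth
from .landscape_core import (
    AreaVector,
    LandUseGrid,
    RedLineMask,
    apply_mask,
    class_areas,
    kappa_agreement,
)

SCENARIO_COLUMNS = ("security", "material", "spiritual", "comprehensive", "ld")


def load_table5() -> pd.DataFrame:
    """Published scenario area table, indexed by class label (km²)."""
    with resources.files("econeeds.fixtures").joinpath("table5.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("class")


def table5_vector(column: str) -> AreaVector:
    """One column of the fixture as an :class:`AreaVector`."""
    df = load_table5()
    return AreaVector(df.loc[list(lc.CLASS_LABELS), column].to_numpy())


def change_table(
    a: AreaVector, b: AreaVector, labels: tuple[str, str] = ("a", "b")
) -> pd.DataFrame:
    """Per-class differences a − b between two area vectors (km²)."""
    if a.class_labels != b.class_labels:
        raise ValueError("area vectors use different class orderings")
    return pd.DataFrame(
        {
            "class": list(a.class_labels),
            f"area_{labels[0]}": a.area_km2,
            f"area_{labels[1]}": b.area_km2,
            "delta": a.area_km2 - b.area_km2,
        }
    )


def redline_report(
    grids: dict[str, LandUseGrid],
    baseline: LandUseGrid,
    mask: RedLineMask,
) -> pd.DataFrame:
    """Per-scenario class areas inside the red line, with deltas vs baseline.

    Rows: one per (scenario, class); columns ``area_km2`` inside the mask and
    ``delta_km2`` relative to the masked baseline.
    """
    base_areas = class_areas(apply_mask(baseline, mask))
    records = []
    for scenario, grid in grids.items():
        areas = class_areas(apply_mask(grid, mask))
        for i, cls in enumerate(grid.class_labels):
            records.append(
                dict(
                    scenario=scenario,
                    **{"class": cls},
                    area_km2=areas.area_km2[i],
                    delta_km2=areas.area_km2[i] - base_areas.area_km2[i],
                )
            )
    return pd.DataFrame(records)


DEFAULT_CONFIG: dict = {
    "synth": {"rows": 60, "cols": 60, "change_fraction": 0.1, "seed": 0},
    "scenarios": ["comprehensive"],
    "demands": "fixture",  # "fixture" | "solve" | path to CSV
    "leas": {"n_per_class": 2000, "trees": 30},
    "cars": {"max_iterations": 300, "seed": 0},
}


def _scaled_demand(column: str, base: LandUseGrid) -> AreaVector:
    """Fixture column re-proportioned onto the synthetic landscape.

    Built-up classes cannot convert under the default transfer rules, so
    their demand is pinned to the base areas and the four ecological classes
    share the remaining area in the fixture column's proportions.
    """
    base_areas = class_areas(base)
    col = table5_vector(column).area_km2
    out = base_areas.area_km2.copy()
    eco = slice(0, 4)
    eco_total = base_areas.total - out[4] - out[5]
    out[eco] = col[eco] / col[eco].sum() * eco_total
    return AreaVector(out)


def run_pipeline(config: dict | None = None, outdir: str | os.PathLike | None = None) -> dict:
    """Run the full synthetic pipeline and return a report bundle.

    Stages: synthetic landscape → per-scenario demands (fixture columns
    re-proportioned, or the LP solver) → LEAS growth probabilities → CARS
    allocation → change tables, red-line report and agreement metrics.
    With ``outdir`` set, writes ``areas.csv``, ``changes.csv``,
    ``redline.csv`` and ``run.json``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    stage = "synth"
    try:
        params = synth.LandscapeParams(**cfg["synth"])
        t0, t1, drivers, redline = synth.generate_landscape(params)

        stage = "demands"
        demands: dict[str, AreaVector] = {}
        for scenario in cfg["scenarios"]:
            if cfg["demands"] == "solve" and scenario != "ld":
                sol = mop.solve_scenario(scenario)
                if sol.status != "optimal":
                    raise RuntimeError(f"{scenario} LP status {sol.status}")
                # re-proportion the solved structure onto the synthetic grid
                base_areas = class_areas(t1)
                frac = sol.areas.area_km2 / sol.areas.total
                demands[scenario] = AreaVector(frac * base_areas.total)
            else:
                demands[scenario] = _scaled_demand(scenario, t1)

        stage = "leas+cars"
        cars_cfg = dict(cfg["cars"])
        rules = _cars.TransitionRules()
        grids: dict[str, LandUseGrid] = {}
        diagnostics: dict[str, dict] = {}
        for scenario, demand in demands.items():
            p = _cars.CarsParams(**cars_cfg)
            grid, diag = _cars.run_scenario(
                t0, t1, drivers, demand, rules, p,
                n_per_class=cfg["leas"]["n_per_class"], M=cfg["leas"]["trees"],
            )
            grids[scenario] = grid
            diagnostics[scenario] = {
                "iterations": diag["iterations"],
                "kappa_vs_base": diag["kappa_vs_base"],
                "final_areas": diag["final_areas"].area_km2.tolist(),
            }

        stage = "accounting"
        base_areas = class_areas(t1)
        areas = pd.DataFrame(
            {"class": list(lc.CLASS_LABELS), "base": base_areas.area_km2}
            | {s: class_areas(g).area_km2 for s, g in grids.items()}
        )
        changes = pd.concat(
            [
                change_table(class_areas(g), base_areas, labels=(s, "base"))
                .assign(scenario=s)
                for s, g in grids.items()
            ],
            ignore_index=True,
        )
        red = redline_report(grids, t1, redline)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "areas": areas,
        "changes": changes,
        "redline": red,
        "diagnostics": diagnostics,
        "config": cfg,
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        areas.to_csv(os.path.join(outdir, "areas.csv"), index=False)
        changes.to_csv(os.path.join(outdir, "changes.csv"), index=False)
        red.to_csv(os.path.join(outdir, "redline.csv"), index=False)
        run_meta = {
            "config": _jsonable(cfg),
            "diagnostics": _jsonable(diagnostics),
        }
        with open(os.path.join(outdir, "run.json"), "w") as fh:
            json.dump(run_meta, fh, indent=2, sort_keys=True)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
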