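# econeeds

Scenario optimization of ecological land: how much arable land, forest,
grassland, water and built-up land should a region hold to satisfy human
**security**, **material** and **spiritual** needs — and where on the map
should each class go?

The package couples two stages over six land-use classes
(arable, forest, grass, water, residential, industrial-mining-transport):

1. **Quantity structure by multi-objective programming (MOP).** Linear
   objectives over the class areas x₁..x₆ (km²):
   - security (ecological-footprint supply):
     `f₁(x) = 0.02x₁ + 0.08x₂ + 0.45x₃ + 0.16x₄`
   - spiritual (green-equivalent share of the regional total S):
     `f₂(x) = (0.33x₁ + x₂ + 0.34x₃ + 0.83x₄)/S`
   - material (economic benefit, RMB):
     `f₃(x) = 362.33x₁ + 13.56x₂ + 168.47x₃ + 235.78x₄ + 45783.88x₅ + 67582.55x₆`

   maximized one at a time — or together as an ideal-point-normalized
   weighted sum `Σ wₘ fₘ(x)/fₘ*` — under planning constraints (fixed total
   area, population-capacity bracket, arable and water floors, built-land
   bracket, per-capita footprint bracket, non-negativity). A
   linear-development (LD) baseline extrapolates per-class OLS trends with
   proportional closure to the total; per-unit economic benefits come from
   GM(1,1) grey forecasting of yearbook series.

2. **Spatial allocation by a patch-generating cellular automaton.** A
   land-expansion analysis (LEAS) extracts, for each class k, the cells that
   converted to k between two epochs, trains a per-class random forest on
   driver surfaces (terrain, accessibility, population, GDP) and scores every
   cell with a growth probability `P_k = votes/M`. The CA (CARS) then
   iterates the overall probability `OP = P_k · Ω_k · D_k` — neighborhood
   share Ω, adaptive demand coefficient D — with random patch seeding
   `P·r·μ·D` where Ω = 0, roulette selection among classes, a decreasing
   competition threshold τ, and transfer rules (built-up land never
   converts; a no-transfer mask freezes protected cells) until every class
   meets its demanded area. Results are audited against an ecological
   red-line mask.

Because the original 30 m rasters and yearbooks are not redistributable, the
package ships a synthetic-landscape generator with *known* ground truth
(driver-driven transitions, published equilibrium factors, controlled
exponential series) plus the published scenario area table as a CSV fixture,
so every stage is testable offline.

## Worked example

```python
import numpy as np
from econeeds import (
    solve_scenario, change_table, table5_vector,
    generate_landscape, LandscapeParams, run_scenario, CarsParams,
)
from econeeds.accounting import _scaled_demand

# published scenario table: security scenario vs the 2020 status quo
delta = change_table(table5_vector("security"), table5_vector("y2020"),
                     labels=("security", "2020")).set_index("class")
print(delta.round(2))
```

```
                             area_security  area_2020   delta
class
arable                             3919.27    3919.27    0.00
forest                            25176.17   24887.55  288.62
grass                              3909.57    4198.31 -288.74
water                               311.17     311.17    0.00
residential                         136.49     136.49    0.00
industrial_mining_transport          28.56      28.56    0.00
```

Only forest and grass interconvert under the security objective: forest
gains 288.62 km² at grassland's expense.

```python
sol = solve_scenario("comprehensive")
print(sol.status, np.round(sol.areas.area_km2, 2), round(sol.objective_value, 4))
# optimal [ 3919.27  0.  10714.06  17893.9  136.49  817.51 ] 0.8246
```

The solver returns the optimum of the *printed* constraint set; it differs
from the published scenario table because that table is not reproducible
from the printed bounds alone (see `docs/methods.md`), which is why the
table ships as a fixture and the solver is validated against an exhaustive
vertex-enumeration oracle instead.

```python
# synthetic landscape: fit LEAS on t0 -> t1, allocate a scenario demand
params = LandscapeParams(rows=100, cols=100, change_fraction=0.1, seed=7)
t0, t1, drivers, redline = generate_landscape(params)
demand = _scaled_demand("comprehensive", t1)
grid, diag = run_scenario(t0, t1, drivers, demand,
                          params=CarsParams(seed=7), n_per_class=2000, M=30)
print(diag["iterations"], diag["final_areas"].area_km2,
      round(diag["kappa_vs_base"], 3))
# 56 [1349. 6652. 1445.  107.  235.  212.] 0.957
```

After 56 CA iterations every class is within one cell of its demanded area
(demand `[1349.1 6651.7 1445.1 107.1 235.0 212.0]` km²), total area exactly
conserved, and the allocated map agrees with the base epoch at κ = 0.957 —
the scenario reshapes ~4% of the landscape.

A `click` CLI mirrors the stages: `econeeds synth | optimize | leas |
simulate | run` (see `--help` on each).

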