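# Methods

## Scope and data model

The package optimizes the structure and layout of six land-use classes,
coded 1–6 in a fixed order (arable, forest, grass, water, residential,
industrial-mining-transport). Grids are plain integer matrices with a scalar
cell area in km² and nodata −1; all area accounting is cell counting, so the
method is projection-agnostic and no geodesy is performed. Two grids are
comparable only when shapes and cell areas match exactly — no silent
resampling. Internal areas are km² throughout; footprint quantities are hm²
(1 km² = 100 hm²) and conversion happens only at the constraint boundary,
because the source material mixes the two units without stating conversions.

## Structure optimization (MOP)

Three linear objectives encode the needs scenarios; their coefficients are
**configuration with published defaults**, not quantities the package
re-derives. In particular the security coefficients (0.02, 0.08, 0.45, 0.16
on classes 1–4) are not algebraically derivable from the equilibrium factors
(1.74, 0.44, 1.41, 0.35) that motivate them, so both sets are carried as
independent published constants. The spiritual objective returns the
dimensionless green-equivalent fraction (e.g. 0.8323 on the 2020 areas);
multiply by 100 for a percentage. Green equivalents g₅ = g₆ = g₇ = 0: built
and unused land carry no landscape-recreation value.

The constraint set transcribes the regional planning bounds literally,
including the population-capacity formula
120·(x₁+x₂+x₃) + 3000·(x₅+x₆) ∈ [4,523,100, 4,618,000] persons — water (x₄)
is excluded from the capacity sum, as printed. Every constraint can be
disabled individually, and any area vector can be audited with signed slack.
This matters because the published optimal solutions do **not** satisfy
every published bound: the security solution's footprint sum (33,316.18 km²)
exceeds the printed upper bound 32,787.82, and the material solution's
residential area (153.27 km²) exceeds the printed cap 143.27 — evidently
unprinted constraints or different bounds were used originally. The package
therefore treats the published scenario table as a versioned fixture
(`fixtures/table5.csv`, transcribed verbatim) that feeds change accounting
and downstream allocation, while the solver itself is validated by
equivalence with an exhaustive vertex-enumeration oracle on random programs.
One transcription note: the published 2020 status-quo column sums to
33,481.35 km², 0.12 above the stated regional total (a rounding residue in
the source table); the five scenario columns sum to the total within
0.05 km². The fixture reproduces the residue rather than "correcting" it.

Scenario solving is `scipy.optimize.linprog` with the HiGHS dual simplex and
fixed options, so repeated runs agree bitwise. The comprehensive scenario
uses ideal-point-normalized weighted sums: each single objective is
maximized alone to get f₁*, f₂*, f₃*, then Σ wₘ fₘ(x)/fₘ* is maximized with
default equal weights. This is a standard, reproducible scalarization chosen
because the source states the joint objective without a method. The LD
baseline is per-class OLS extrapolation of the historical areas, floored at
zero, then closed proportionally to the fixed regional total (the published
LD column sums to the total, so closure is implied).

### Grey forecasting

GM(1,1) is fitted conventionally: one accumulation, background values
z(k) = ½(x¹(k)+x¹(k−1)) with the standard coefficient ½, least squares for
(a, b) in x⁰(k) + a·z(k) = b. Forecasting solves the fitted *difference*
equation exactly — ratio r = (1 − a/2)/(1 + a/2) per step — rather than the
continuous whitening equation's e^{−a}. The two differ at O(a³); the
discrete response reproduces exponential inputs exactly (machine-precision
forecasts on noiseless geometric series), which is the property the model is
relied on for here. The fitted a relates to a continuous rate α by
a = 2·tanh(α/2), so parameter recovery is exact to first order and within
1e−6 for |α| ≲ 0.02. Constant series hit the a → 0 branch and forecast the
constant b.

## Synthetic landscapes

The generator stands in for three decades of classified rasters and their
driver surfaces. Default class fractions mirror the study region's 2020
composition (forest 74.3%, grass 12.5%, arable 11.7%, water 0.93%,
residential 0.41%, industrial 0.16%); the default grid is 100×100 cells of
1 km², with 200×200 used where rare-class sample sizes matter.

* **Epoch t0** — each class owns a smoothed Gaussian score field
  (correlation length 6 cells); classes claim their cell quota from rarest
  to commonest by taking their highest-scoring unassigned cells. This yields
  exact fractions and clustered patches (patch structure is required for the
  neighborhood effect to be non-degenerate), at the cost of slightly
  irregular patch boundaries for the last (largest) class.
* **Drivers** — seven smooth surfaces scaled to [0, 1] named dem, slope
  (gradient magnitude of dem), dist_rail, dist_road, dist_river,
  pop_density, gdp, grouped into the security/spiritual/material needs
  taxonomy; pop_density and slope belong to two groups each and contribute
  half their importance to each group.
* **Epoch t1** — a `change_fraction` (default 0.1) of cells convert; the
  destination class is sampled from a softmax over per-class linear scores
  on the **standardized** drivers, so the weights are effect sizes per
  driver standard deviation. Each class leans 3× on one designated driver
  (class 1 → dem, class 2 → slope, …), making the true importance ranking
  known. Standardization matters: the smoothed [0, 1] surfaces have ~0.15
  s.d., and without it the nominal weights would act on a compressed scale
  and the designed ground truth would not be identifiable.
* **Red line** — the forest∪water union eroded or dilated toward 40%
  coverage, reduced to its largest connected component. With the
  forest-dominant defaults the union starts near 75%, so erosion is the
  usual direction.

What the generator does **not** emulate: real geography (valleys, road
networks, cities), autocorrelated *conversion* timing, class-specific patch
geometry, measurement/classification error, or realistic magnitudes for
population and GDP. Passing tests therefore demonstrate that the estimators
and the allocator recover designed structure under clean conditions — not
that they would rank real drivers correctly on real rasters.

## Expansion analysis (LEAS)

For class k, positives are cells with t0 ≠ k and t1 = k; cells already k at
t0 are ineligible for both labels (the expansion map marks them −1).
Balanced sampling (default cap 5,000 per label) draws equal positives and
negatives without replacement; the rates are unstated in the source and are
configuration. The per-class model is a random forest of M = 50 trees with
√d features per split; the growth probability is the explicit vote ratio
votes/M computed per tree, not the library's averaged leaf probabilities, so
the definition holds regardless of leaf purity. Importances are
impurity-based, normalized to sum one. Classes never observed to expand
(typically built-up land under transfer restrictions) receive a flat 0.5
surface in the all-class fit instead of an error, since such classes are
normally also barred from growing by the transfer rules.

## Allocation (CARS)

Demands are converted to exact cell targets (rounding residue assigned to
the largest class). Each iteration:

1. Per deficit class k: Ω_k is the share of k in the 3×3 window (center
   excluded; edge cells divide by the clipped in-bounds count; nodata cells
   count in the denominator as not-k). OP = P_k·Ω_k·D_k; where Ω_k = 0 a
   seed is attempted with probability 0.1 (expansion coefficient), and if
   the uniform draw r < P_k the seeding branch OP = P_k·r·μ_k·D_k applies
   with patch threshold μ = 0.5. The window size is unstated in the source;
   3×3 is the default.
2. Candidate cells are mutable (not frozen, transfer allowed) members of
   surplus classes. A roulette wheel over the class OPs nominates one target
   class per cell; ties break toward the lower class code. Nominations with
   OP ≥ τ are applied in descending OP order (cell index as tie-break) while
   the target class is still below and the donor class still above their
   exact cell targets.
3. τ starts at 1 and halves whenever an iteration converts nothing, so
   high-probability conversions happen first and competition loosens
   gradually.
4. The adaptive coefficient follows a gap-ratio inertia rule (the source
   names the feedback but gives no formula): with gap G = demand − area, D
   is unchanged while |G| does not grow, scaled by G_now/G_prev when the gap
   grows with unchanged sign, and clipped to [0.1, 10].
5. Once τ decays below 1e−9, any residual deficit is filled
   deterministically by shedding surplus cells with the lowest retention
   probability (own-class OP), lowest first. This is also the mechanism for
   demanded *shrinkage*, which the source's growth-only description does not
   cover. With the expansion coefficient at 0 the fill is restricted to
   cells adjacent to existing patches, preserving the no-spontaneous-patch
   property.

Conversions aim at the exact cell targets; the demand tolerance (default
0.1% of total area) is only a termination fallback once allocation has
genuinely stalled — aiming at the tolerance instead can deadlock a donor
class whose surplus equals the sum of several within-tolerance deficits.
Total cell count is conserved exactly at every iteration (asserted), frozen
cells are bit-identical by construction, and the whole loop is deterministic
under the seed. Default transfer rules fix built-up land entirely (no
conversions in or out): scenario demands for those classes must equal their
current areas, and the pipeline pins them accordingly when re-proportioning
the published scenario columns onto a synthetic grid. Unreachable demands
(growth of a class no rule allows into, shrinkage of one no rule allows out
of) fail fast naming the class.

Map agreement uses Cohen's kappa over all jointly valid cells with expected
agreement from the marginal class frequencies; the source does not state its
cell sampling, so no subsampling is applied.

## Problem sizes and limitations

The test and acceptance runs use 200×200 grids for driver-recovery
statistics (≈ 700–900 expansion cells for a rare class at 10% change) and
100×100 grids for allocation studies, ten seeds each — sizes at which the
recovering statistics are stable while a full run stays in seconds. Known
limitations: the published scenario optima are not re-derivable from the
printed objective/constraint set (documented above, audited rather than
reproduced); single-horizon allocation only (no multi-epoch dynamics); one
global τ rather than per-class thresholds; red-line reporting on synthetic
masks cannot reproduce the published red-line areas, which depend on the
real protected-area geometry.
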