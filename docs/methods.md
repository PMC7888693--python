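# Methods

## Model

The package measures *potential* spatial accessibility: what could be
reached given supply capacities, population counts and car travel times —
not utilization, affordability or acceptability. The index unit is
opportunities (practitioners) per person, inherited from the
container-based FCA family.

The MH3SFCA pipeline is three group-by reductions over the sparse set of
in-catchment demand–supply pairs:

1. `Huff_ij = S_j W_ij / Σ_k S_k W_ik` — interaction probabilities. The
   denominator runs over the supply sites reachable from `i`; since all
   capacities and weights are strictly positive it is positive whenever at
   least one site is reachable, so the probabilities of each covered
   location sum to exactly 1 (in floating point: to ≤ 2⁻⁵² observed).
2. `R_j = S_j / Σ_i Huff_ij D_i` — capacity per allocated person.
3. `A_i = Σ_j Huff_ij R_j W_ij` — distance-weighted share of ratios.

Two consequences are tested as invariants rather than assumed:
*demand conservation* (`Σ_ij Huff_ij D_i` = total covered population) and
the *suboptimality bound* (`Σ_i A_i D_i ≤ Σ_j S_j`, equality only at zero
distances). The latter separates MH3SFCA and M2SFCA from the conserving
2SFCA/E2SFCA/3SFCA lineage and operationalizes the claim that treating
the realized demand–supply ratio as optimal overestimates access.

All pairwise quantities live in one long-format table keyed by
`(demand_id, supply_id)`. A realistic regional run has 10⁷ pairs, so dense
demand × supply matrices are out; the dense formulation exists only as an
independently written triple-loop oracle in the test suite.

## Distance decay

Weights come from the Gaussian kernel `f(d) = exp(-d²/β)` with
`β = d_max²/ln(1/w_min)`. Parameters, units and defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `d_max` (min) | catchment threshold | 30 | standard acceptable car travel time to primary care in well-developed road networks |
| `w_min` (–) | weight at `d_max` | 0.01 | the threshold weight is rarely reported in applied studies; 0.01 is a conventional near-zero floor, and it is an explicit, recorded parameter precisely because published index magnitudes cannot be compared without it |
| `mode` | `continuous` / `subzones` | continuous | the continuous per-pair weighting is the method's point; subzones reproduce the older discrete scheme |
| `n_zones` | subzone count | 4 | the discrete scheme historically used four bands |

Subzones are equal-width, left-closed/right-open bands over `[0, d_max]`
(last band closed, so `d = d_max` is in-catchment, matching the `≤ d_max`
convention everywhere); each band is weighted at its midpoint. When every
observed distance coincides with its band midpoint the two modes agree
exactly — a tested convergence property.

## Travel times

Edge cost is `minutes = length_m × 0.06 / speed_kmh` from static speed
limits; one-way streets are modelled by the absence of the reverse edge.
OD matrices use multi-source Dijkstra (scipy csgraph) pruned at `d_max`,
with inclusive comparison (`t ≤ d_max`; scipy's `limit` keeps
equal-to-limit nodes, verified). Travel direction is population → supply
throughout, and that same `t_ij` is used in every step — patients travel
to providers, and a single consistent matrix keeps the three steps
coherent on asymmetric (one-way) networks.

Points snap to the nearest network node by Euclidean distance, ties broken
to the smallest node id. Nearest-node (rather than nearest-edge) snapping
is deliberate: grid-cell spacing is typically below edge length, and it
keeps snapping deterministic and dependency-free. Coordinates must be
planar meters; no CRS handling is performed.

A Euclidean constant-speed OD builder exists for data without a network
and for tests; it shares the threshold semantics.

## Degenerate inputs

- Demand with no in-catchment supply: `A_i = 0` (zero encodes "no
  access"), counted in run metadata, never dropped silently.
- Supply with no in-catchment demand (or only zero-population cells):
  `R_j = 0` plus a logged warning — island sites must not abort a run.
- Zero-population cells still receive an index (access exists even where
  nobody lives) but contribute nothing to any denominator.
- Zero-capacity supply rows are rejected at load time.
- No rounding anywhere in the pipeline; the eight-decimal display
  truncation (toward zero, via `decimal` to avoid binary artifacts) is
  purely an output-formatting step, and result CSVs carry full doubles
  (`%.17g`, read back with round-trip parsing).

## Quantile classification

Class `r` of `k` collects values between the `(r−1)/k` and `r/k`
empirical quantiles (linear-interpolation definition, ties to the lower
class). GIS packages differ in their break conventions, so absolute class
boundaries are not comparable across software — only orderings are; the
convention here is fixed and documented for that reason.

## Synthetic regions

The generator emulates the *structure* of the data such studies use, not
any particular place: a 100 m-cell population grid whose cell counts are
Poisson draws around a monocentric density (centre peak 60 per cell,
exponential e-folding radius 2 km, rural floor 0.4 per cell — peak urban
block densities and a sparse countryside at plausible German magnitudes,
totalling ~130k inhabitants on the default 12 × 12 km extent); empty cells
are dropped, mirroring unpopulated land cover. Forty practice sites with
1–5 practitioners each are placed 80% population-proportionally / 20%
uniformly. The road lattice (600 m spacing, speed classes 30/50/60/80
km/h) turns 15% of streets one-way, refusing any flip that would break
strong connectivity, so every catchment remains well-defined.

Presets: `monocentric` (defaults above), `two-town` (two centres ~7.5 km
apart on a 15 km extent), `uniform` (flat density, unclustered supply).
Determinism is part of the contract: one integer seed fixes all draws,
and identical configurations reproduce byte-identical files (metadata
sidecars deliberately contain no timestamps).

What the generator does *not* emulate: real OSM topology (detours,
missing links, dead ends), demographic structure, daytime population
shifts, tourism-driven demand, and edge effects at study-area borders
(the synthetic region is closed; real administrative regions leak demand
and supply across their boundary). Tests passing on synthetic regions
therefore validate the mathematics and the pipeline, not any empirical
claim about a real region.

### Resolving polycentric structure

The two-town preset exhibits two distinct accessibility maxima only when
the catchment is smaller than the inter-town spacing; with a 30-minute
car catchment both towns fall inside every location's reach and the
surface flattens toward a single interior ridge. The polycentricity check
therefore analyses the preset at a 10-minute threshold (≈6.7 km at
40 km/h against ~7.5 km spacing). This is a property of catchment methods
generally, worth knowing when choosing `d_max` for small study areas.

## Problem sizes

Default verification sizes: 200 random instances of ≤ 30 demand × ≤ 20
supply for oracle-equivalence and conservation checks, 50 random directed
graphs of ≤ 50 nodes for shortest-path equivalence, and the full
monocentric region (~14k locations, ~560k pairs) for the end-to-end and
urban–rural checks — large enough to exercise the sparse paths, small
enough that the whole suite runs in well under a minute.

## Known limitations

- Single travel mode (car, static speed limits); no congestion, turn
  penalties or public transport.
- Nearest-node snapping can mis-assign points near long edges.
- β and `d_max` are behavioural parameters; results shift with them, and
  absolute index magnitudes are only comparable between runs sharing both.
- No edge-effect correction: supply/demand outside the input extent is
  invisible, biasing indices near borders of real study areas.
- The Gaussian kernel is the only implemented decay; the `DecayParams`
  seam would admit others, but none are tested.
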