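# fcaccess

Floating catchment area (FCA) methods for quantifying **potential spatial
accessibility** of healthcare supply — how many practitioners are, in
effect, available per person at every population location, given where
supply sits, where people live, and how long it takes to drive between
them. The package is aimed at health-geography and health-services
researchers who want a reproducible, scriptable alternative to running
these methods inside a desktop GIS.

Its centrepiece is the **modified Huff-model three-step FCA (MH3SFCA)**
with *continuous* per-pair Gaussian distance decay; the classic variants
(2SFCA, E2SFCA, 3SFCA, M2SFCA) are included for comparison, along with a
directed road-network travel-time engine and seeded synthetic study
regions so the entire pipeline runs without any proprietary data.

## The method

Travel impedance enters through a Gaussian kernel
`f(d) = exp(-d²/β)`, with the *coefficient of friction* β derived from the
catchment threshold `d_max` so that the weight at the threshold equals a
chosen floor `w_min`: `β = d_max² / ln(1/w_min)`.

With `W_ij = f(d_ij)` for every pair within `d_max`, the three steps are

1. **Huff interaction probabilities** — location *i* splits its demand over
   reachable sites by capacity × weight:
   `Huff_ij = S_j W_ij / Σ_k S_k W_ik`.
   Rows sum to 1, so total demand is conserved: demand only shifts away
   from a distant site when alternatives exist.
2. **Supply–demand ratios** —
   `R_j = S_j / Σ_i Huff_ij D_i` (practitioners per allocated person).
3. **Accessibility index** —
   `A_i = Σ_j Huff_ij R_j W_ij` (practitioners per person at *i*).

Because `W_ij ≤ 1` appears again in step 3, aggregate access
`Σ_i A_i D_i` never exceeds deployed capacity `Σ_j S_j`, with equality only
at zero travel times — a spatially suboptimal configuration of sites
delivers less access than the capacity it deploys. Binary 2SFCA, by
contrast, redistributes capacity exactly.

## Worked example

```bash
python examples/04_accessibility_pipeline.py
```

runs the full pipeline on the seeded monocentric synthetic region
(12 × 12 km, 100 m population grid, 40 practices, road lattice with
one-way streets) and prints:

```
locations:            14032
zero-access:          0
min index:            0.00054477
max index:            0.00081021
mean index:           0.00071548
pop-weighted mean:    0.00075298

central quarter (pop-weighted mean): 0.00078332
peripheral quarter:                  0.00065045
urban advantage: 1.20x
```

Indices are practitioners per person (multiply by 100 000 for "GPs per
100k"); every location has non-zero access because the road lattice is
strongly connected and the region is smaller than the 30-minute catchment.
The central-vs-peripheral contrast is the urban–rural accessibility gap
the method is designed to expose. `examples/05_method_comparison.py`
contrasts all five methods on the same region and shows the conservation
(2SFCA-family) versus suboptimality (M2SFCA, MH3SFCA) behaviour.

The same pipeline is available from the shell:

```bash
fca simulate --preset monocentric --seed 42 --out scn/
fca odmatrix --nodes scn/nodes.csv --edges scn/edges.csv \
             --demand scn/demand.csv --supply scn/supply.csv \
             --dmax 30 --out od.csv
fca access --method mh3sfca --od od.csv --demand scn/demand.csv \
           --supply scn/supply.csv --dmax 30 --wmin 0.01 --classes 5 --out run/
fca report --result run/result.csv
```

Every command writes a JSON metadata sidecar (parameters, seed, input
digests); identical configurations reproduce byte-identical outputs.

## Layout

- `src/fcaccess/decay.py` — Gaussian kernel, friction coefficient, subzone scheme
- `src/fcaccess/network.py` — road graph, snapping, thresholded Dijkstra OD matrices
- `src/fcaccess/core.py` — the three MH3SFCA steps over sparse interactions
- `src/fcaccess/baselines.py` — 2SFCA, E2SFCA, 3SFCA, M2SFCA
- `src/fcaccess/synthetic.py` — seeded synthetic regions (monocentric, two-town, uniform)
- `src/fcaccess/io.py`, `report.py`, `cli.py` — file formats, quantile classes, summaries, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
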