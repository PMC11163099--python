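# Methods

## Model and procedure

The pipeline has three stages.

1. **Descriptors.** Every supported topological index is an edge-weight sum
   TI(G) = Σ_{uv∈E} f(d_u, d_v), so it is computed from the degree-pair edge
   partition: TI = Σ_{(i,j)} count(i,j)·f(i,j). A partition is either supplied
   directly (the bundled study compounds carry their partitions) or derived
   from a graph by tallying the canonical pair (min(d_u,d_v), max(d_u,d_v))
   per edge. A second, independent route (`brute_force_index`) iterates edges
   without building a partition; the two routes are held equal to 1e-12
   relative tolerance in property-based tests.

2. **Regression.** For each property P ∈ {melting point, formula weight} and
   each index, a univariate OLS model P = A + B·TI is fitted in closed form
   (B = Sxy/Sxx, A = ȳ − B·x̄). Inference: r = Sxy/√(Sxx·Syy) (tables report
   |r|; the slope keeps its sign), r², F = r²(n−2)/(1−r²), p = upper tail of
   F(1, n−2) (equivalent to the two-sided t test on the slope, t² = F),
   standard error of the estimate √(SSres/(n−2)), and a significance label at
   p < 0.05. With n = 5 compounds these are desk-scale computations; the
   closed forms are cross-checked in tests against statsmodels OLS and a
   normal-equation solver, and the F tail against numeric quadrature of the
   F density.

3. **Report.** `run_qspr` assembles six table families (descriptors,
   correlations, per-model statistics, standard errors, one
   actual-vs-computed table per property, and the reported-deltas table) and
   writes them as full-precision CSV. Report generation is a pure function of
   the input bytes and options.

## The modified second Zagreb index

The descriptor tables this package reproduces compute mM2 with the edge
weight 1/(d_u+d_v) — verifiable from the worked sums, and implying the exact
identity H = 2·mM2 — whereas the wider literature defines mM2 with
1/(d_u·d_v). The default follows the reproduced tables;
`mm2_variant="literature"` (CLI `--mm2-variant literature`) selects the
textbook weight. For study compound 1 the two give 5.588 and 5.639.

## Reported-value deltas

Recomputing the descriptor table from the study compounds' edge partitions
reproduces every integer-weight cell (M1, M2, HM, F) exactly and most
2-decimal cells within rounding (±0.015, since the original rounding
direction is not always consistent — 5.588 appears as 5.58). Thirteen cells
disagree beyond rounding (for compound 4's reciprocal Randić index by nearly
a full unit); these look like arithmetic slips in the original calculations,
though a partition misprint cannot be excluded without the atom-level
structures. The package always reports the recomputed value and lists every
divergent cell, with both values, in `reported_deltas.csv` — no divergence is
silent. Downstream, the originally reported regression coefficients for the
float-valued indices chain from the slipped 2-decimal descriptor values;
models driven by the integer-weight indices are unaffected, and those are the
rows the golden tests pin.

## Synthetic data generator

`random_molecular_graph` emulates hydrogen-suppressed heavy-atom skeletons:
it grows a random spanning tree under a degree cap (default 4, the maximum
degree observed in the study compounds), then adds a small number of
ring-closing edges (expected ≈0.15·n, giving tree-like molecules with a few
rings). `synth_compounds` draws graph sizes uniformly from a vertex range
(default 18–30, bracketing the study compounds' 24–28 heavy atoms) and
generates the target property from the same linear model the regression
assumes, P = A + B·TI + N(0, σ²) (defaults A = 400, B = −1.5 on M1, σ = 5 —
property and slope scales comparable to the melting-point models), while the
other property is drawn independently of structure (Normal(360, 35²)) to
exercise the weak-correlation regime observed for formula weight. All
randomness flows from one integer seed; outputs are bit-identical across
runs.

What the generator does **not** emulate: chemical validity beyond the degree
cap (no valence rules, no element identities, no realistic ring statistics),
measurement error structure in the properties beyond i.i.d. Gaussian noise,
and any dependence between the two properties. Passing recovery tests
therefore demonstrates the statistical machinery is correct under the model's
own assumptions, not that the linear model is adequate for real compounds.

## Numerical choices

- Degree pairs are stored canonically (d_u ≤ d_v); inputs may use either
  order.
- ABC at d_u = d_v = 1 is 0 (vanishing radicand), not an error.
- A perfect fit (r² = 1 within 1e-14) reports F = +inf and p = 0 with a
  `boundary` flag rather than failing, keeping the pipeline total.
- Degenerate inputs raise typed errors: fewer than 3 observations, a
  constant predictor, or a constant response; in the correlation table a
  degenerate cell is annotated NaN instead of failing the whole table.
- CSVs carry full precision; rounding to the displayed 2 decimals happens
  only in human-readable rendering, never before comparison.
- r is clipped to [−1, 1] to absorb floating-point overshoot before squaring.

## Design choices

- The printed edge partitions, not hand-drawn structures, are the canonical
  compound data: partitions are reproducible from the source tables, whereas
  re-deriving atom-level adjacency from structure drawings is not.
- The statsmodels-style Model/Results split (`TopoIndexQSPR` / `QSPRResults`)
  presents each property-on-index regression as a fitted model with a
  `summary()` row, while module-level helpers (`fit_all_models`,
  `correlation_table`, `prediction_table`, `run_qspr`) cover the batch
  workflow.
- 22 models are fitted and tested marginally, with no multiple-testing
  correction — deliberately matching the reproduced workflow; with 22
  marginal tests at α = 0.05 the family-wise error rate is far above 5%, a
  documented limitation.
- Significance is a fixed p < 0.05 threshold; the labels, not prose claims,
  are treated as the authoritative convention.

## Problem sizes

Property-based tests use 100 seeded random graphs of ≈18–25 vertices per
invariant; recovery experiments use 200 replicates of 30 compounds (σ = 5)
for the noisy case and 12–15 compounds for the noiseless case; the
correlation-vs-noise check uses 100 replicates of 10 compounds at σ ∈
{0, 1, 10}. The full suite and the acceptance script each run in well under
a minute on one CPU.

## Known limitations

- n = 5 compounds gives 3 residual degrees of freedom: the inference is
  fragile, and the package reproduces it rather than endorses it.
- Univariate linear models only; no cross-validation, applicability domain,
  or multivariate extension.
- No structure parsing (SMILES/SDF), aromaticity or stereochemistry; the
  graph model is purely topological.
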