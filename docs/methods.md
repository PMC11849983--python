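# Methods

This note records the algorithmic conventions, parameter defaults, and
numerical design choices of the `tipc` package. Everything here is a
deliberate package-level decision; where a convention is one of several
defensible options, the alternative and the reason for the choice are
stated.

## 1. Hexagonal tessellation

Samples are partitioned into regular **flat-top** hexagons of side length
`s`. In axial coordinates `(q, r)` the hexagon center is

```
x = ox + 1.5·s·q          y = oy + √3·s·(r + q/2)
```

with the `(0, 0)` center anchored at the bounding-box minimum of the
sample's cells (`ox, oy`). Anchoring at the data's own bounding box makes
the partition translation-covariant: translating all cells by any vector
re-anchors the grid identically, so the resulting subregion composition
is unchanged.

A point is assigned to the hexagon whose center is nearest (the hexagons
are the Voronoi cells of their centers). The implementation converts the
point to fractional axial coordinates, cube-rounds to a candidate index,
then checks the candidate and its six neighbors by exact squared
distance; ties (points equidistant from two centers, i.e. exactly on an
edge) are broken toward the lexicographically smallest `(q, r)` so that
assignment is a total, deterministic function. The test suite verifies
this against two independent oracles: brute-force nearest-center search
over all candidate centers, and polygon containment of explicitly
constructed hexagons.

**Grid shifts.** For robustness analysis the grid is re-laid four more
times with the origin displaced by half a side length: left/right (∓x)
and up/down (±y). The five variants (center + 4 shifts) are used both in
the size-selection objective and as replicate vectors during clustering.

**Subregion size selection (`optimal_hex_len`).** The sweep covers sides
30, 35, 40, 45 µm (≈2.3–5.8·10³ µm² per hexagon — roughly 10–60 cells at
typical tissue densities, large enough to hold a meaningful local ratio,
small enough to resolve aggregates). For each size `s` two scores are
computed from the cohort mean vectors: `B(s)`, the variance across the
six parameters of the center-grid cohort mean (low = no single category
saturates the signature — an informative partition), and `R(s)`, the mean
over parameters of the variance across the five shift variants (low =
insensitive to arbitrary grid placement). The chosen size minimizes
`rank(B) + rank(R)`, ties resolved toward the smaller (finer) size.

## 2. The six-parameter signature

Global ratios `gIT = N_I/N_T` and `gIS = N_I/N_S` are the sample's own
null model of neutral mixing. Each non-empty hexagon is classified by
comparing its local ratio to the global one:

- tumor present, no immune → `tumor_only`; stroma present, no immune →
  `stroma_only` (a mixed tumor/stroma hexagon without immune cells counts
  once on each side);
- tumor and immune present → `it_high` if `n_I/n_T > gIT` else `it_low`;
  likewise for stroma with `gIS`;
- immune-only hexagons have local ratio +∞ on both sides and count as
  `it_high` and `is_high`;
- exact ties (`n_I/n_T = gIT`) go to "low": the hexagon shows exactly the
  neutral mixing the null model predicts, so it is not evidence of
  enrichment.

Counts are divided by the number of non-empty hexagons. Since a hexagon
contributes at most one category per side (tumor side, stroma side),
each element is in [0, 1] and the element sum is in [1, 2].

**Integer comparisons.** `n_I/n_T > gIT` is evaluated as the
cross-multiplication `n_I·N_T > N_I·n_T` in integer arithmetic. This
makes the tie rule and the signature's invariances exact rather than
subject to floating-point division error. The float formulation gives the
same answer except within one ulp of a tie; the integer form removes
that caveat entirely.

**Multiple ROIs.** When a sample has several regions of interest, each
ROI is tessellated separately (its own bounding box), category counts are
summed across ROIs, and normalization happens once at the end; the global
ratios use the pooled cell totals. This treats the ROIs as disjoint
windows of one tissue rather than as separate samples.

**Replacement mode.** The classifier only sees three slots. Mapping a
second immune phenotype onto the "stroma" slot in the phenotype mapping
profiles immune–immune partitioning with no code change; the reader
validates only that mapping targets are the three slot names.

## 3. Consensus clustering of cohorts

Vectors are compared by Pearson correlation distance `d = 1 − r`
(composition *shape* matters, not magnitude). For each candidate cluster
number `k` in 2–6, the cohort is subsampled `reps = 50` times at
`frac = 0.8` without replacement, each subsample is clustered by
agglomerative hierarchical clustering cut at `k`, and the consensus
matrix entry `M_k[i,j]` is the fraction of co-sampled repetitions in
which `i` and `j` co-clustered. Final labels at each `k` come from
complete-linkage clustering of `1 − M_k`.

**Inner linkage: average, not complete.** The linkage used *inside* the
resampled runs is average linkage (the classical consensus-clustering
default), while finalization on the consensus matrix uses complete
linkage. This asymmetry is deliberate. With complete inner linkage, the
k→k+1 transition on a clean G-group cohort splits one group by its
diameter in a way that is *stable across subsamples*; a stable
refinement increases the area under the consensus CDF by the mass of the
split pairs, so the delta-area curve never flattens at the true k and
the shoulder criterion systematically overshoots (measured Δ(k+1) ≈
0.03–0.08 on planted three-group cohorts, never below the 0.025
threshold, across 20 seeds and several group geometries). Average
linkage makes within-group refinements unstable (they follow the noise),
the consensus gain collapses (measured Δ(4) ≈ 0.008–0.018 on the same
fixtures), and the shoulder lands at the planted k.

**Choosing k.** `A(k)` is the exact area under the empirical CDF of the
upper-triangle consensus entries (computed as a step integral, not a
Riemann approximation). `Δ(k)` is the relative gain `(A(k) −
A(k−1))/A(k−1)` (and `Δ(k_min) = A(k_min)`). The **shoulder** is the
smallest `k` whose successor gains less than `τ = 0.025`. From the
shoulder, `k` is extended upward while consecutive partitions stay
consistent (NMI ≥ `η = 0.9`, arithmetic-mean normalization); the largest
such `k` is `optimal_k`. Note the extension rule is permissive by
design: on a perfectly clean cohort, splitting one tight group keeps NMI
≈ 0.98, so `optimal_k` can exceed the planted `k`; the shoulder is the
conservative estimate and both are reported.

**Outliers.** After cutting at the chosen `k`, clusters smaller than
`max(30, ⌈0.03·n⌉)` samples are relabeled "outlier"; remaining clusters
are renamed "1", "2", … by descending size. The absolute floor of 30
reflects the smallest subgroup for which downstream per-subtype analyses
(e.g. survival) are plausible at cohort scale; for small demonstration
cohorts it must be lowered explicitly (`min_abs`), which is a conscious
speed bump rather than a silent adaptation.

## 4. Subtype transfer (extrapolation)

A `SubtypeModel` stores the reference vectors, their subtype labels
(outliers removed — "outlier" is an absence of a subtype, not a
transferable class), and the subregion size the vectors were computed
at. Query samples, vectorized at the *same* size (enforced), are
assigned the majority label among their `k = 10` nearest reference
vectors in Euclidean distance; a tied vote falls back to the single
nearest neighbor's label. The model serializes to a single zip archive
of two CSVs plus a metadata JSON — human-inspectable and
version-control friendly.

## 5. Benchmark comparators

All comparators use the sample's bounding box as the observation window.

- **NND**: median distance from each immune cell to its nearest tumor
  cell (KD-tree).
- **Morisita–Horn**: on a square grid (default 5 µm) anchored at the
  bounding-box minimum, with per-square counts `x_i`, `y_i`:
  `MH = 2Σx_iy_i / ((Σx_i²/X² + Σy_i²/Y²)·X·Y)`; 1 for identically
  distributed counts, 0 for disjoint occupancy.
- **G-cross**: ECDF of tumor-to-nearest-immune distances, optionally
  with the reduced-sample (border) correction that drops tumor cells
  closer than `r` to the window edge.
- **K/L-cross**: `K(r)` is estimated with a choice of three classical
  edge corrections — Ripley's isotropic correction (closed-form
  circumference weights on a rectangle, valid for `r` up to half the
  shorter window side, enforced), the translation correction
  `A/((W−|dx|)(H−|dy|))`, and the border method. `L(r) = √(K(r)/π)`
  equals `r` under complete spatial randomness, which the test suite
  verifies to within 5% over 50 Poisson simulations for all three
  estimators.
- **AUC**: radial curves are summarized by trapezoidal area over
  `r ∈ [0, 20]` µm (0.5 µm grid) — the neighborhood scale of direct
  cell–cell interaction.
- **Dichotomization**: per-metric high/low splits use the
  linear-interpolation quantile (default 80th percentile) with strict
  `>` for "high", so an all-ties cohort is uniformly "low".

## 6. Synthetic data generator

Tissues are generated in a 1000×1000 µm window: tumor cells uniform in a
union of disk "glands", stromal cells rejection-sampled uniformly in the
complement, immune cells either uniform over the window ("disperse") or
uniform in a few 50 µm foci ("clustered"). Two morphologies are
provided — stromal-predominant (8 glands of radius 60 µm, 900 tumor /
2700 stroma cells) and variable-mixed (20 glands of radius 80 µm, 2100
tumor / 1400 stroma) — with 400 immune cells by default, matched within
clustered/disperse pairs so the conditions differ *only* in immune
placement. Densities (≈3–4·10³ cells/mm²) are in the range of real
multiplexed imaging data. Limits: glands are independent disks (they may
overlap; no ducts/annuli), the window is rectangular with no holes or
tissue folds, and compartment counts are exact rather than Poisson. The
generator is a test fixture for the algorithms' contracts, not a tissue
model.

Vector cohorts for clustering tests use three archetypes that are cyclic
permutations of one base profile, so the planted groups are
exchangeable under the correlation metric and the planted `k` is
unambiguous. All generators are pure functions of their spec, seeded via
`numpy.random.SeedSequence`.

## 7. Numerical and determinism choices

- **Bit-identical reruns.** Every pipeline output is written with
  `float_format="%.10g"` and a provenance header (`# tipc <version>
  config=<sha256-prefix>`); rerunning with the same config yields
  byte-identical files. The run log (wall-clock timestamps/timings) is
  the one exception and is excluded from the determinism contract.
- **Scale invariance** of the signature (scaling coordinates and `s`
  together) is exact for power-of-two factors, where binary floating
  point multiplication is error-free; for other factors it holds up to
  points within ~1 ulp of a hexagon boundary.
- **Translation invariance** under lattice-vector shifts is likewise
  exact except for boundary-ulp points; for continuous uniform
  coordinates the probability of such a point is ≈10⁻⁶ per fixture, and
  the test fixtures are frozen seeds verified to contain none.
- **Problem sizes** in tests and the acceptance script (10⁴ points for
  the geometry oracle, 100 tissues for the vector contracts, 20
  replicate pairs, 150-sample planted cohorts, 50 CSR simulations,
  200-sample end-to-end runs) are the package's own choices, sized to
  give stable pass/fail behavior in a few minutes on one CPU.

## 8. Parameter defaults (summary)

| Parameter | Default | Rationale |
|---|---|---|
| size sweep | 30–45 µm, step 5 | 10–60 cells per hexagon at tissue density |
| grid shifts | ±s/2 in x and y | half-side displacement maximally perturbs boundaries |
| tie rule | low | a tie is exactly the null model's prediction |
| k range | 2–6 | cohort-scale subtype counts; ≥7 rarely survives outlier filtering |
| reps / frac | 50 / 0.8 | classical consensus-clustering defaults |
| τ (delta-area) | 0.025 | relative consensus gain regarded as noise |
| η (NMI) | 0.9 | consecutive partitions "consistent" |
| outlier floor | max(30, 3% of n) | smallest subgroup usable downstream |
| kNN | k = 10, Euclidean | majority vote robust to single mislabeled references |
| M-H grid | 5 µm | ≈ single-cell-diameter quadrats |
| AUC radius | 20 µm | direct-interaction length scale |
| px→µm | 2 px/µm | common 0.5 µm/px imaging resolution |
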