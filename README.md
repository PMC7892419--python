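# distinctfish

Trait-based analysis of functional distinctiveness in marine fish
communities.  The package is aimed at community ecologists working with
long-term bottom-trawl surveys who want to know *which species carry
unique trait combinations*, *where and when those species occur*, and
*how their dynamics relate to environment, fishing pressure, extinction
risk and shared ancestry*.

## What it computes

Functional distinctiveness of species *i* in a pool of *N* species is

> Di = Σ_{j≠i} d_ij / (N − 1)

where `d_ij` is the Gower dissimilarity between the species' mixed
(continuous + categorical) trait vectors.  Around this index the package
provides the full analysis chain:

- **`traits`** — trait-table validation and the Gower matrix (pairwise
  deletion of missing values, range standardization, weights);
- **`distinctiveness`** — `Di`, deterministic ranks, quartile pools
  (Q1 = functionally common, Q4 = functionally distinct; `ceil(N/4)`
  species each, so a 130-species pool has 33 distinct species), and
  Spearman/Wilcoxon trait-association tests;
- **`community`** — pool-level richness/abundance per grid cell and year,
  time-averaged maps, whole-system annual series, and per-cell /
  per-species Spearman trends of log abundance against year;
- **`ordination`** — redundancy analysis from first principles with three
  designs (spatial, temporal, spatio-temporal) plus a seeded permutation
  test for the constrained variance share;
- **`vulnerability`** — chi-square homogeneity of IUCN categories between
  pools, Spearman correlation of `Di` with 0–100 fishing-vulnerability
  scores, threatened fractions;
- **`phylo`** — Brownian-motion covariance from a Newick tree and PGLS
  with fixed or ML-estimated Pagel's λ;
- **`simulate`** — a seeded scenario generator (species pool, grid,
  environment, survey, phylogeny, statuses, ground truth) so the entire
  chain is testable without external data;
- **`pipeline` / CLI** — end-to-end orchestration with a reproducibility
  manifest.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Generate a full synthetic scenario (130 species, 154 cells, 33 years),
compute distinctiveness, and relate pool abundances to the environment:

```python
from distinctfish import SynthConfig, simulate_scenario, gower_matrix
from distinctfish import compute_distinctiveness, assign_quartile_groups, membership
from distinctfish import group_site_year_metrics, build_spatial_design, fit_rda

bundle = simulate_scenario(SynthConfig(seed=1))
dm = gower_matrix(bundle.traits, bundle.schema)
di = assign_quartile_groups(compute_distinctiveness(dm))
print(di.sort_values("rank", ascending=False).head(3)[["species", "Di", "group"]])

member = {s: g for s, g in membership(di).items() if g in ("Q1", "Q4")}
series = group_site_year_metrics(bundle.survey, member)
result = fit_rda(build_spatial_design(series, bundle.env))
print(f"spatial RDA variance explained: {result.proportion_constrained:.3f}")
print(result.biplot_scores.round(2))
```

This prints:

```
    species        Di group
83    sp084  0.574641    Q4
85    sp086  0.551538    Q4
100   sp101  0.542032    Q4
spatial RDA variance explained: 0.999
              RDA1  RDA2
sst_c        -0.99  0.01
sss_psu       1.00 -0.02
depth_m       0.99  0.01
bstress      -0.99  0.01
pci          -0.99 -0.05
effort_hours -0.96  0.21
```

The three most distinct species all sit in Q4 with `Di` well above the
pool average, and the first ordination axis is the planted north–south
gradient: pool abundances align with deep, saline, cold, low-effort
waters at one end and warm, productive, heavily trawled waters at the
other, which is exactly the structure the generator planted.

The same chain is available from the shell:

```sh
distinctfish simulate --seed 1 --out scenario/
distinctfish distinct --traits scenario/traits.csv \
    --schema scenario/trait_schema.json --out distinctiveness.tsv
distinctfish run --config run.yaml     # full pipeline, 10 artifacts
```

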