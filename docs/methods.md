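# Methods

## The index

Functional distinctiveness of species *i* in a regional pool of *N*
species is the mean trait dissimilarity to every other species:

    Di = Σ_{j≠i} d_ij / (N − 1)

with `d_ij` the Gower dissimilarity between species *i* and *j*.  A species
with a trait combination unlike the rest of the pool has a high `Di`.
Because each `d_ij` lies in [0, 1], so does `Di`; no further rescaling is
applied by default.  An optional mode divides every `d_ij` by the observed
maximum before averaging, for users who prefer the most dissimilar pair to
sit exactly one unit apart — this changes the scale of `Di` but never the
ranks, so quartile pools are identical under both modes.

## Gower dissimilarity over mixed traits

Continuous traits contribute `|x_it − x_jt| / range_t`, the range taken over
the pool's observed values; categorical traits contribute a 0/1 mismatch.
Per-trait terms are combined as a weighted mean (default weights 1).
Missing values follow Gower's pairwise-deletion rule: a trait missing in
either species of a pair is dropped from both the numerator and the weight
sum, which keeps `d_ij` inside [0, 1] without imputation.  A continuous
trait whose pool range is zero carries no information and is excluded for
every pair.  A pair sharing no observed informative trait is an error, not
a silent zero.  Categorical traits are treated as nominal throughout; no
ordinal coding is attempted.

## Quartile pools

Species are ranked by `Di` (ties broken lexicographically by species id so
results are fully deterministic).  Q4 holds the `ceil(N/4)` species of
highest `Di` — 33 species when N = 130 — and Q1 the `ceil(N/4)` of lowest
`Di`; the remainder splits at its median rank into Q2 (lower half, rounded
up) and Q3.  Q1 is read as the functionally common pool and Q4 as the
functionally distinct pool.

## Trait associations

Continuous traits are tested against `Di` with Spearman rank correlations.
For n ≤ 9 complete pairs the two-sided p-value is exact, obtained by
enumerating all permutations of one margin (average ranks are recomputed
under each permutation, so ties are handled exactly); larger samples use
the classical t approximation.  Categorical traits are tested with all
pairwise two-sided Wilcoxon rank-sum tests of `Di` between modalities,
exact when both groups have ≤ 10 members and the pooled values are
tie-free, with a normal approximation otherwise.  Modalities with fewer
than two species are excluded (recorded as warnings) and p-values are
Holm-adjusted across modality pairs — a conservative, assumption-free
correction chosen because the family of pairwise tests can be large.

## Aggregation and trends

The survey is long-format: one record per (species, cell, year) with
abundance in individuals per km²; an absent record means zero.  Pool-level
richness (members with strictly positive abundance — no minimum-abundance
threshold) and total abundance are computed per cell-year, averaged over
the years each cell was actually surveyed for maps, and summed across cells
for whole-system annual series.  Temporal trends are Spearman correlations
of log(abundance + 1) against calendar year; the natural log with a +1
offset keeps zero catches finite, and since Spearman is a rank statistic
the transform does not alter ρ — it matters only for the ordination
responses.  Cells or species observed in fewer than 3 years yield no trend
(skipped, logged); constant series keep a missing ρ with the reason
recorded.  Per-species trends use annual totals zero-filled over the full
survey period, but a trend is only reported for species observed in at
least 3 distinct years, so a single stray record never generates a
spurious trend.

## Redundancy analysis

RDA is implemented from first principles: center the response matrix Y,
center and standardize predictors X to unit variance (they mix °C, m,
hours; standardizing leaves the constrained proportion invariant but
stabilizes biplot scores), fit Ŷ = X_c B by multivariate least squares via
a rank-revealing SVD (pseudo-inverse with relative singular-value tolerance
1e-10; effective rank reported), then eigendecompose cov(Ŷ) for the
constrained axes and cov(Y_c − Ŷ) for the residual axes.  The constrained
share of total variance is the headline "variance explained".  Eigenvalue
sums conserve the total variance of centered Y to 1e-9 relative error, and
eigenvalues below 1e-12 of total variance are reported as zero.  Fits are
refused when the row count cannot exceed the centered predictor rank plus
one, where the constrained proportion would be trivially 1.  Site scores
are principal coordinates of Ŷ; response scores are eigenvectors, scaled
by √λ in scaling 2 (the default correlation-biplot); biplot scores are
correlations of each predictor with the site scores.  The reported
proportion is raw, not adjusted for predictor count.

Three designs are provided: spatial (rows = cells; responses = log mean
pool abundance; predictors = time-averaged SST, SSS, depth, bed shear
stress, PCI, effort — the basin-wide NAO/AMO indices are excluded because
they are spatially constant), temporal (rows = years; responses = log
whole-system annual abundance; predictors = annual spatial means plus NAO
and AMO, depth excluded as time-constant), and spatio-temporal (rows =
cells; responses = the per-cell trend ρ of each pool; spatial predictors).
Rows with missing entries are dropped at design build, never imputed, and
constant predictors are dropped with a warning.

A seeded permutation test for the constrained proportion is included
(p = (1 + #{perm ≥ observed}) / (n_perm + 1), rows of Y permuted jointly).
Since permuting rows changes neither the column means nor the total sum of
squares, each permutation only needs the squared projection of Y onto X's
orthonormal column basis, which keeps 999 permutations effectively free.

## Phylogenetic regression

Under Brownian trait evolution the covariance of two tips equals the
branch length their root-to-tip paths share; the covariance matrix is
built by assigning each internal node its root distance and filling tip
pairs that split there (any stem edge below the root is not counted as
shared history).  PGLS solves the generalized least squares problem by
whitening with the Cholesky factor of C(λ), where Pagel's λ scales the
off-diagonal of C; λ defaults to 1 (pure Brownian) because the source
analysis names the method but not a correlation model, and may be set to
any value in [0, 1] or estimated by bounded ML search (tolerance 1e-6,
with an explicit check of both boundary values).  Inference uses t
statistics on n − p degrees of freedom.  If the Cholesky factorization
fails, the diagonal is jittered once by 1e-10·trace/n.  A binary
threatened/not response is fitted with the same Gaussian machinery as a
linear probability model; a phylogenetic logistic model is deliberately
out of scope, and the pipeline skips the regression when the binary
response is constant among tree species.

## The scenario generator

The generator emulates the statistical structure the analysis assumes, not
any real data set.  Defaults: 130 species (97 common + 33 distinct
archetype), a 14 × 11 grid of 154 cells (1° lon × 0.5° lat, from 51°N),
33 annual surveys from 1983.  Continuous traits are log-normal around
archetype means separated by well over 2 SD (e.g. age at maturity 2.2 vs
9 years, fecundity 2×10⁵ vs 70, offspring size 1.3 vs 32 mm); categorical
modalities are drawn with archetype-specific probabilities (distinct:
mostly pelagic/benthopelagic, piscivorous, high parental care; common:
demersal, benthivorous, little care) — the K- versus r-selected syndromes
of the study system.  The environment has north–south gradients (north
deeper, colder, more saline, less productive, less trawled), SST warming
of 0.06 °C/yr and trawling effort declining 4.5 %/yr.  Expected log
abundance is a species baseline plus archetype-specific coefficients on
the standardized environment/effort fields plus an archetype-specific
year trend, with multiplicative log-normal noise (matching the
analysis-side log transform); a detection threshold is subtracted and
values floored at zero, which generates the zero-inflation of real trawl
data.  The phylogeny is a Yule tree (unit depth, ultrametric) over a
93-species subset; the status table tilts vulnerability weakly and the
threatened-category probability strongly towards the distinct archetype.

All draws descend from one integer seed through fixed substream offsets,
so adding a generator never perturbs another's stream and equal seeds give
byte-identical exports.  What the generator does *not* emulate: haul-level
sampling, gear catchability, species interactions, spatial autocorrelation
of the noise field, and range shifts.  Passing recovery tests therefore
demonstrates that the chain detects the planted structure under the
model's own assumptions — not that it would recover the same figures from
real survey data.

## Numerical conventions

- Rank ties anywhere are resolved deterministically (lexicographic species
  id); reruns with identical inputs are byte-identical.
- Gower distances are symmetrized (0.5·(D + Dᵀ)) and clipped to [0, 1] to
  absorb floating-point asymmetry before validation.
- The RDA orientation of an axis is arbitrary; recovery checks orient the
  first axis so the distinct pool's response score is positive before
  comparing biplot signs.
- Chi-square homogeneity uses no continuity correction (tables are
  generally wider than 2 × 2); a warning is attached when any expected
  count is below 5 rather than switching to an exact test.
- Problem sizes in the test suite (e.g. 100 random Gower tables, 200
  permutation-test datasets, 100 full-scale scenario seeds, 200 PGLS
  replicates) were chosen to make the Monte-Carlo bounds sharp while
  keeping the whole suite comfortably fast on one CPU.

## Known limitations

- Abundance-weighted distinctiveness variants (uniqueness, scarcity) are
  out of scope.
- The linear probability coding of IUCN status ignores the bounded nature
  of the response; with strong phylogenetic signal in a rare binary trait
  its standard errors are approximate.
- Partial RDA, forward selection and adjusted R² are not provided; the
  reported proportion rises mechanically with predictor count.
- The generator's planted effects act on the log-mean only; there is no
  mechanistic density dependence, so "rebound" scenarios are purely
  phenomenological.
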