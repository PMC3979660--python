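# Methods

## Model

`wssmap` estimates household coverage of three indicators — use of an
improved drinking-water source, use of improved sanitation, and open
defecation — at the second administrative level (admin2) from cluster-level
survey counts. Each indicator is modelled independently with a hierarchical
binomial logistic regression:

- **Likelihood.** A survey site contributes `k ~ Binomial(n, p)` with
  `logit(p) = α[c,r] + β[c,r](t − t0) + u_j + v_a`. `n` counts households
  with a non-missing response. Sites located only to admin1 are replicated
  over the m admin2 of that admin1 with weight 1/m each; weights enter as
  powers on the likelihood, so the total information mass is conserved
  exactly (splitting a record into two half-weight copies leaves the
  posterior kernel unchanged to machine precision).
- **Country level.** Intercepts and linear time slopes are
  stratum-specific (rural/urban) and drawn around grand means with
  between-country SDs: countries with little data shrink toward the
  regional trend; countries with many surveys follow their own data.
- **Spatial level.** `u` follows an intrinsic CAR (ICAR) prior on the
  within-country admin2 adjacency graph with country-specific SD
  `σ_u[c]`: each district's effect, given its neighbours, is normal with
  mean the neighbour average and variance `σ_u²/m`. The ICAR is improper;
  a sum-to-zero constraint per connected component identifies it, and
  districts with no neighbours (islands) are fixed at 0 and excluded from
  the ICAR sum. The pseudo-likelihood exponent for `σ_u` uses the ICAR
  rank (nodes − components).
- **Admin1 level.** `v` is an iid normal effect with one global `σ_v`,
  capturing non-spatial dependence of sites within a province.
- **Sharing.** `u` and `v` are shared across the urban/rural strata; only
  intercepts and slopes are stratum-specific. This is the parsimonious
  choice; a stratified spatial field would roughly double the spatial
  parameter count with no synthetic-data evidence it is needed.

**Hyperpriors** (all on the logit scale, configurable): grand means
`N(0, 5²)`; every SD half-normal(1). These are weakly informative for
proportions: ±2 prior SD on a grand mean spans essentially the whole unit
interval, and a logit-scale SD of 1 already allows admin2 coverage to range
over ~50 percentage points within a country.

`t0 = 2012` by default, so intercepts are directly the logit coverage in
the prediction year, which also decorrelates nothing by itself — the
sampler additionally re-centres time internally (below).

## Sampling

Inference is by adaptive Metropolis-within-Gibbs, written so that one full
replicate at the package's standard synthetic scale (3 countries × 54
admin2, 324 sites, 2 chains × 4 000 iterations) runs in a few seconds:

- element-wise random-walk Metropolis for `α`, `β`, `u`, `v`, vectorised
  over conditionally independent blocks. The `u` updates use chromatic
  blocking: the adjacency graph is greedily coloured, and within one colour
  class no two districts are adjacent or share a record, so the whole class
  updates in one vectorised step;
- an internal reparameterisation `α_int = α + β·t̄` (precision-weighted
  mean survey time per country × stratum cell) removes the strong
  intercept–slope correlation induced by a reference year outside the data
  span; draws are transformed back before storage;
- an exact Gibbs move along the likelihood-invariant ridge
  `α[c,·] += δ, v[a ∈ c] −= δ` resolves the weak identification between
  country intercepts and admin1 effects;
- conjugate Gibbs draws for the grand means; tuning-free slice sampling on
  the log scale for every SD; and ASIS-style interweaving moves that
  rescale `u` (per country) and `v` jointly with their SDs, which breaks
  the funnel coupling between small SDs and near-zero effects;
- proposal scales adapt during warmup toward 0.4 acceptance
  (Robbins–Monro, rate `t^-0.6`) and are frozen afterwards;
- after each `u` sweep the per-component sum-to-zero constraint is
  re-imposed by centring (standard ICAR practice); islands stay exactly 0.
  Stored draws therefore satisfy the constraint at every iteration.

Chains are seeded from a single `SeedSequence`; identical seeds give
byte-identical draws. Convergence is monitored by rank-normalised split
R-hat and bulk ESS (via arviz), with a 1.05 flag threshold; at the standard
synthetic scale max split R-hat ≈ 1.03.

## Prediction and aggregation

For a target year (default 2012), coverage per admin2 × stratum is
`expit(α + β(year − t0) + u + v)` per posterior draw. Districts without
data get `u` drawn per draw from the exact joint Gaussian conditional of
the ICAR given the observed effects of their graph component (block solve
of the Laplacian precision system, not single-site sweeps); a component
with no observed district falls back to `u = 0` (basis `imputed`, warned),
and a country with no admin2-located data is predicted at admin1 resolution
(basis `admin1-level`, spatial effect omitted). Admin1 that contributed no
data receive a posterior-predictive `v ~ N(0, σ_v²)` draw — the model is
silent about them beyond exchangeability, and omitting the term would
understate uncertainty.

Overall coverage per district is the urban/rural population-weighted mean;
national coverage is the population-weighted mean over districts, computed
per draw so the conservation identity holds exactly. Districts with zero
total population are excluded from national sums and reported as missing.
Significance flags compare each district to the national mean through the
per-draw difference: `low`/`high` when the central 95% interval of the
difference excludes 0 — a coherent single-probability statement, rather
than non-overlap of two marginal intervals.

## Inequality

Per country, districts are ranked ascending by per-capita coverage (ties
broken by district id for determinism) and the cumulative share of use
(population × coverage) is plotted against the cumulative population
share. The GINI coefficient is twice the area between this Lorenz curve and
the diagonal, computed by the trapezoid rule
`G = 1 − Σ (q_i − q_{i−1})(L_i + L_{i−1})`; this equals the
population-weighted pairwise mean-absolute-difference formula to 1e−12,
which the tests verify by brute force. Ranking by per-capita coverage
(rather than by raw share of national use) is the standard Lorenz
construction and guarantees the curve lies below the diagonal; raw-share
ranking is available as a sensitivity option. All-zero national use is an
error rather than a defined GINI.

GINI is computed per posterior draw of the overall coverage surface (a
point-estimate mode exists). The cross-country regression of GINI on
national coverage is ordinary least squares fitted once on posterior
medians; RGI per draw is `G(draw) − expected(median coverage)`, and a
country is flagged when the central 95% interval of RGI excludes zero.
Fitted values are clipped to [0, 1] only for display; residuals are always
computed on the unclipped line. For open defecation, GINI/RGI are computed
on the complement (access to any sanitation) so the indicator points the
same way as the others.

## Synthetic data

The generator emulates the structure the analysis assumes: countries of
stacked admin1 blocks, each a rook-contiguity lattice of admin2 (queen
optional; real data can supply an explicit edge list); urban/rural
populations per admin2 (log-normal totals around 200 000 persons, Beta(2,3)
urban share); country intercepts/slopes around stratum grand means; ICAR
spatial effects realised through the graph-Laplacian pseudo-inverse
(the proper representative of the improper ICAR, supported on the
sum-to-zero subspace); iid admin1 effects; and binomial cluster sampling
with 25 households per site (a typical DHS cluster take), with each site's
stratum Bernoulli in the admin2 urban share. Configurable fractions of
admin2 receive no sites and of sites are emitted located to admin1 only.

Default grand means put 2012 coverage near 60% (water), 40% (sanitation)
and 25% (open defecation) with urban populations better served and slow
secular improvement; between-country SDs are 0.75 (intercepts) and 0.02/yr
(slopes); σ_u = 0.5, σ_v = 0.3. The standard test scenario uses 3
countries × 2 admin1 × (3×3 lattice), survey years {1998, 2005, 2011}, 2
sites per admin2-year — 324 sites, ~8 100 households.

What the generator does **not** emulate: GPS-located clusters and
point-in-polygon allocation, survey-design effects (PSU/strata weights,
non-response), non-sampling error, reporting bias in self-reported use,
population rasters (population enters at admin2 resolution), and secular
deviations from a linear logit trend. Passing tests therefore demonstrate
internal consistency of the estimator under its own assumptions, not
robustness to these real-data complications.

## Numerical and design choices

- Binomial log-likelihood computed via `k·η − n·softplus(η)` with
  `softplus = logaddexp(0, ·)` for stability; the binomial coefficient is
  included (scaled by the record weight).
- Non-positive SDs evaluate to −∞ (a rejected state), not an exception.
- ICAR draws and conditionals: eigen-decomposition with a 1e−9 null-space
  cut-off for simulation; Cholesky block solves for imputation.
- Classification of survey response categories is exact string matching
  after lower-casing and whitespace collapsing, against a packaged YAML
  vocabulary with a synonym-extension mechanism; unknown categories
  classify as unimproved and are logged. Pit latrines of unknown slab
  status count as unimproved; sharing does not demote the main sanitation
  indicator (a private-improved variant is computed where sharing is
  known). "Accessible" water defaults to ≤1 km or ≤15 minutes one-way,
  both thresholds configurable.
- The accessible-water and private-sanitation variants are summarised
  nationally but not spatially modelled (their data availability is much
  lower in real surveys).
- Pipeline outputs are CSV at 6 significant digits plus full-precision
  .npy draw stores with a JSON manifest of input/output hashes, seed and
  versions; all randomness derives from one top-level seed split per
  stage, so a rerun reproduces every output hash.
- Problem sizes in the test suite: the replicated recovery experiment uses
  20 replicates of the standard scenario at 2 chains × 4 000 iterations;
  the significance-flag experiment uses 2 × 20 replicates at 2 chains ×
  2 500 iterations, which is ample for flag stability though not for
  hyperparameter tails.

## Known limitations

- With only 3 countries, the posterior for a stratum grand mean is driven
  by 3 country intercepts; when those happen to cluster, the
  between-country SD shrinks and the grand-mean interval can under-cover a
  fixed generating truth (~90% realised coverage in the recovery
  experiment at that scale; nominal at 10 countries). This is inherent to
  few-group hierarchies, not a sampler defect.
- Metropolis-within-Gibbs mixing degrades for much larger graphs; a
  gradient-based backend targeting the same posterior kernel would be the
  natural extension.
- The RGI regression ignores uncertainty in the fitted line (it is fitted
  once on posterior medians); only GINI uncertainty propagates to RGI
  intervals.
- Admin1-only records are spread uniformly (1/m) over their admin2 rather
  than population-proportionally; with strongly unequal district
  populations this slightly over-weights small districts.
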