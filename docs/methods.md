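# Methods

## Data model

The unit of analysis is an areal unit (here, a county) with an observed case
count `Y_i`, a population at risk, a covariate vector, and an expected count
`E_i`.  The bundled Georgia table stores *mean annual* case counts as
published; the modelling pipeline first converts them to five-year period
totals (`round(cases × period_years)`, `period_years = 5` for the 2012–2016
window, configurable) so that `Y_i` is an actual count with Poisson-scale
variability.

Expected counts use internal (indirect) standardization against the pooled
study rate: `E_i = population_i × Σ_j Y_j / Σ_j population_j`.  This is the
standard disease-mapping default when no external reference rates or
age-structured populations are available, and it makes `Σ E_i = Σ Y_i` an
exact identity, so the population-weighted mean SMR is 1 by construction.
Age-standardized expected counts against an external reference are
deliberately out of scope; with internal standardization every relative risk
is interpreted against the pooled Georgia rate for the same period.

Two counties (Ben Hill, Jeff Davis) are missing five covariate cells each.
The default policy keeps all 159 rows and imputes each missing cell with the
column mean over observed counties, logging a warning; a strict policy that
rejects missing data is available.  Covariates are standardized (zero mean,
unit SD over observed areas) before fitting, so coefficients are per-SD
effects and the Gaussian prior scale is meaningful for all of them, income
included.  The descriptive "all counties" summary aggregates every column by
the unweighted mean over observed counties — including the income column,
where the reported statewide figure is the mean of the county medians.

## Adjacency

The ICAR prior needs a symmetric binary neighbourhood graph.  Graphs come
from GAL files, plain edge lists, or queen contiguity computed from GeoJSON
polygons (two areas are neighbours when their polygons share at least one
boundary point; an STRtree keeps this O(n log n)).  Queen contiguity is the
common default for US county models; the analysis does not depend on the
rook/queen choice for lattices used in validation, where adjacency is rook
(interior degree 4) by construction.  Disconnected graphs are supported —
every connected component carries its own sum-to-zero constraint — and
degree-zero islands are allowed, with their spatial effect pinned at 0.

## The models

Non-spatial:  `Y_i ~ Poisson(E_i θ_i)`, `log θ_i = β₀ + x_i'β`.

BYM convolution:  `log θ_i = β₀ + x_i'β + u_i + v_i`, where `u` follows the
intrinsic CAR distribution — conditionals `u_i | u_{-i} ~ N(ū_δi, σ_u²/n_δi)`,
joint density `∝ σ_u^{-(n-G)} exp(-Σ_{i~j}(u_i-u_j)²/(2σ_u²))` with `G` the
number of graph components — and `v_i ~ N(0, σ_v²)` i.i.d.

Priors (defaults, all configurable):

| parameter | prior | default rationale |
|---|---|---|
| β₀ | flat | absorbs the overall level; internal standardization already centres it near 0 |
| β_k | N(0, 1/0.001) | weakly informative on standardized covariates |
| 1/σ_u², 1/σ_v² | Gamma(1, 5·10⁻⁵) | classic vague disease-mapping precision prior |

These are documented stand-ins for "software default" vague priors; with 159
areas and five-year counts the likelihood dominates the fixed-effect
posteriors (posterior means match the Poisson MLE to three decimals on the
Georgia data).

The classic BYM caveat applies: `u` and `v` are identified only through
their sum, so per-area summaries of either component alone are weakly
identified and should be read qualitatively.  The relative risks `θ`, their
exceedance probabilities, and `β` are the identified outputs.

## Sampler

Adaptive Metropolis-within-Gibbs:

* Random-walk Gaussian proposals for `β₀`, each `β_k`, each `u_i`, each
  `v_i`.  Step sizes adapt by Robbins–Monro (`log s ← log s + t^{-0.6}(acc −
  0.44)`) during burn-in only and are frozen afterwards, so post-adaptation
  draws come from a fixed, valid kernel.
* Latent-field updates are *chromatic*: a greedy colouring of the adjacency
  graph yields classes with no internal edges; all sites of one colour have
  mutually independent full conditionals given the rest and are updated as
  one vectorised block.  The kernel is identical to a site-by-site sweep in
  colour order.  `v` is a single block (no cross-site coupling).  Likelihood
  deltas use cached `E_i exp(η_i)` so each update is O(class size).
* Conjugate Gibbs draws for the precisions:
  `1/σ_u² ~ Gamma(a + (n−G)/2, r + ½ Σ_{i~j}(u_i−u_j)²)` and
  `1/σ_v² ~ Gamma(a + n/2, r + ½ Σ v_i²)`.
* After every sweep `u` is re-centred to mean zero within each component
  (the standard identifiability fix for the improper ICAR; the flat
  intercept absorbs the level, and nothing else is adjusted).
* Chains are seeded from independent `SeedSequence` spawns of one master
  seed; every run is bit-reproducible given the seed.

Defaults: 4 chains × 20,000 iterations, 10,000 burn-in, thin 5.  The Georgia
fits in the analysis scripts use shorter, checked runs (R-hat reported and
gated at 1.05 in the pipeline's strict mode; rank-normalized split R-hat per
scalar parameter, computed with ArviZ).

Degenerate inputs: areas with `Y_i = 0` are fully supported (the Poisson
log-likelihood stays finite for θ > 0); `E_i ≤ 0` is rejected; a constant
covariate is rejected before sampling; non-finite sampler states abort with
the iteration index.

## Synthetic data and what validation shows

`simulate_dataset` draws from exactly the model the sampler fits: Gaussian
covariates per area, an ICAR field sampled *exactly* via the spectral
decomposition of `Q = diag(n_δ) − A` (null modes removed, so draws have
covariance `σ_u² Q⁺` and sum to zero per component), i.i.d. Gaussian `v`,
uniform populations, and `E_i` from an explicit baseline rate (default 150
per 100,000) so the generating parameters are unambiguous.  Fitting then
re-derives `E_i` by internal standardization, mimicking real use — which is
why the intercept is not a recovery estimand (the standardized offset
absorbs it) and the recovery tables report `β`, `σ_u²`, `σ_v²` only.

The default validation setting — chosen once as a realistic mid-size study —
is a 20×20 rook lattice (400 areas), `β₀ = 0.1`, one covariate with
`β = 0.3`, `σ_u = 0.5`, `σ_v = 0.1`, 50 replicates at a reduced MCMC length
(2 chains × 2,500).  Observed performance: ~95% coverage of the 95% CI for
`β` with |bias| < 0.01, and ~90% coverage for `σ_u²`.  `σ_v²` mixes slowly
when its true value is near zero (the usual funnel between a variance and
its near-zero random effects) and its interval coverage is noticeably below
nominal at short chain lengths; conclusions about `σ_v²` need long chains.

What passing these tests does *not* show: the generator draws covariates
independently of space, uses binary contiguity and a correctly specified
likelihood, so validation says nothing about confounding by spatially
structured covariates, overdispersion beyond the BYM effects, or errors in
the real adjacency/geography inputs.

## Summaries and maps

Relative-risk summaries are posterior means with 95% equal-tailed (quantile)
intervals — not HPD — matching common practice in Bayesian disease-mapping
software.  Exceedance probabilities `P(θ_i > c)` use the strict inequality;
default thresholds are 1, 1.5 and 2.  A covariate is "significant" when its
95% equal-tailed interval excludes zero.  Effect densities are Gaussian KDEs
on a fixed 512-point grid.

Choropleths bin values at explicit break points (defaults: RR breaks 0.5,
0.75, 1, 1.25, 1.5, 2, 3; exceedance breaks 0.2, 0.5, 0.8, 0.95 — these are
presentation defaults, configurable) with a sequential palette whose darkest
red marks the top bin.  Static maps are matplotlib SVG/PNG, rendered
deterministically (fixed SVG hash salt, no embedded dates).  Interactive
maps are single self-contained HTML files (inline SVG, radio-button layer
toggles, per-area tooltips with RR, CI and exceedance values) that work
offline.

## Known limitations

* County geometry is not bundled, so the full spatial analysis of the
  Georgia table requires a user-supplied GeoJSON; without it the package
  reports the unsmoothed SMRs and the non-spatial model.
* Internal standardization only; no age adjustment.
* Binary contiguity weights only (no distance-band or k-nearest schemes).
* Classic BYM parameterization; the BYM2/Leroux reparameterizations and
  model-comparison criteria (DIC/WAIC) are future work.
* Mean imputation of missing covariates ignores imputation uncertainty
  (two counties here, so the effect is negligible).
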