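# Methods

This note documents the models and procedures implemented in `forestscape`,
the choices made where a design was genuinely open, and what the synthetic
data do and do not establish.

## Landscapes and metric definitions

A landscape is the set of raster cells whose *centers* lie within Euclidean
distance *r* of a count location (cell-center containment is simple and
unambiguous; the alternative — fractional cell weighting — changes metrics
by at most one cell ring and complicates every adjacency definition).
Landscapes that cross the raster boundary raise an error rather than being
silently truncated; callers pre-filter locations, and the pipeline samples
or retains only locations at least the largest radius from the edge, so
every location carries complete landscapes at all scales.

Map units are kilometres throughout (cells default to 0.03 km, emulating
30 m land-cover products); the default radii are 0.2, 0.5, 1, 2, 4, 6, 8,
10, 12, and 16 km, spanning territory to natal-dispersal scales for
passerines. All radii are configurable.

Configuration metrics use documented conventions rather than any particular
desktop package's unstated defaults:

* **Patch density** — connected components of the focal class within the
  disc, 8-neighbor connectivity (the common default for class-level patch
  metrics; 4-neighbor is available), divided by landscape area (km²).
* **Clumpiness** — rook (4-neighbor) adjacencies tallied from each focal
  cell to neighbors inside the disc, ordered pairs; `G_i = g_ii / Σ g_ik`,
  and `CLUMPY = (G_i − P_i)/P_i` when `G_i < P_i` and `P_i < 0.5`, else
  `(G_i − P_i)/(1 − P_i)`. The boundary-correction term some
  implementations add to `G_i` at extreme proportions is omitted; the
  brute-force pair-scan oracle in the test suite defines the contract.
  Clumpiness is reported missing when the class covers 0% or 100% of the
  landscape — no finite value is defensible there — and missingness
  propagates to the models as listwise deletion for every scale (see
  below). Raster edges contribute only interior adjacencies; there is no
  wraparound.
* **Edge density** — shared rook edges between forest and developed cells,
  both inside the disc, times cell size, per landscape area.

## Composite indices

Both PCA indices operate on the correlation matrix (inputs standardized
with the sample sd). PCA signs are arbitrary, so each component is anchored:
URB is oriented to correlate positively with total developed proportion,
URBHI with the high-intensity developed proportion, H1 with Shannon cover
diversity, H2 with edge density. Anchoring makes scores comparable across
scales and replays.

Urbanization components are retained by the Kaiser–Guttman criterion
(eigenvalue > 1). Retention is data-driven per scale, so URBHI may exist at
some scales and not others; models include it only where it exists. If no
urbanization eigenvalue exceeds 1 (possible on weakly developed synthetic
mosaics), the first component is retained anyway with a warning, because
downstream models require a URB column. The heterogeneity index always
returns its first two components regardless of eigenvalues, since the
models name both.

A zero-variance input (e.g. no high-intensity development anywhere at a
small scale) raises an error naming the variable rather than producing a
degenerate component.

## Guild classification

At each scale, locations are ranked by forest amount ascending (ties broken
by location id) and two nondecreasing curves are compared: the cumulative
share of a species' individuals and the cumulative share of forest amount.
The statistic is `D = max_k |F_species(k) − F_forest(k)|`, with the signed
gap at the first argmax carrying direction.

Counts over locations are not exchangeable draws from a continuous
distribution, so the classical KS null is inapplicable. Significance comes
from a permutation test that shuffles the count vector over locations —
preserving the count multiset exactly — with
`p = (1 + #{D_perm ≥ D}) / (B + 1)`, B = 999 by default. Per scale:
significant with a negative gap → area-sensitive; significant with a
positive gap → edge/open; otherwise generalist. The final label is the
majority over scales, with ties resolved to generalist (the least
committal label). The majority rule and the tie-break are this package's
documented choices; alternatives (e.g. labeling from the single scale with
largest D) are easy to build from the per-scale evidence table.

Note the test's resolving power at tiny n: with 10 locations and two
occupied, the null has only 45 distinct placements and even the most
extreme concentration cannot reach p < 0.05 two-sidedly; significance at
survey-sized location sets is what the classifier is for. Classification
uses the *full* location table, before the forest-cover landscape filter,
so guild definitions reflect the whole gradient of forest amounts.

Species enter classification only if they occur (count > 0) at a minimum
number of locations (default 30, inclusive); generic exclusion flags
(hybrid / irregular / raptor / waterfowl) can remove further species.

## Diversity measures

Per location and guild (area-sensitive, generalist, and their union):
relative abundance (integer sum of counts), Chao1 estimated richness, and
Pielou evenness. Chao1 uses the classic form `S_obs + F1²/(2F2)` with the
bias-corrected fallback `S_obs + F1(F1−1)/2` when F2 = 0, so the estimator
is always finite; the named estimator has several variants and the fallback
matches common package behaviour. Evenness uses natural logs and `S_obs`
(not Chao1) in the denominator — Pielou's standard definition — and is
reported missing when fewer than two species are observed; such locations
are dropped only from models of that response. Richness estimated from a
single 6-minute count underestimates the local pool; Chao1 is used as a
comparable index across locations, not an absolute richness claim.

## Models and scale selection

Responses are modelled with Gaussian linear models (OLS, identity link) on
transformed responses. The negative-inverse transform is applied to
right-skewed responses (by default the area-sensitive relative abundance
and richness and the generalist richness) and is implemented zero-safe as
`y → −1/(y + 1)`, since abundances and richness can be 0; the strict
`−1/y` variant is available for strictly positive responses. All
explanatory variables are standardized (mean 0, sd 1, sample sd) so
coefficients are comparable effect sizes; a raw predictor's scaling
therefore cannot affect its standardized β. Wald 95% CIs use ±1.96 se.

Each scale's model contains the landscape predictors (FA, FPD, FCI, URB,
URBHI where retained, AG) and the per-scale heterogeneity components
measured at that scale, plus scale-free covariates: land-use change,
dominant habitat, observer, start time, date, and year. Categorical
covariates enter as fixed-effect dummies with the most frequent level as
reference. Listwise deletion is applied jointly across *all* scales before
fitting, so every scale's model uses the same location set and AICs are
comparable; the scale with minimal AIC wins, exact ties going to the
smaller radius. Variance inflation factors are reported for every
continuous predictor (auxiliary regression on all other columns). No
multiple-testing correction is applied. Locations enter the models only if
forest amount at the smallest radius is at least 0.5 (inclusive) and the
location lies more than the largest radius from the raster edge.

## Importance ranking

Per response, each landscape-structure component — amount (FA),
configuration (FPD, FCI), matrix quality (URB, URBHI, AG) — is represented
by its meaningful effect (95% CI strictly excluding 0; an interval touching
0 exactly does not qualify) of largest |β|. Components with representatives
place first/second/third by |β|; when exactly two components are
meaningful, the remaining component is placed third; a response with at
most one meaningful component contributes only that placement; ties in |β|
across components are broken amount > matrix quality > configuration with a
warning (ties are measure-zero on real data).

The overall ordering follows the per-rank reading "the component placed
first most often is most important, the one placed second most often is
second, the one placed third most often is third". Because the three
per-rank winners need not form a permutation (two components can tie on
firsts while one dominates seconds), the ordering is resolved jointly as
the assignment of components to ranks that maximizes total agreement with
the placement counts, scanning candidate permutations in the fixed
tie-break order. A lexicographic rule (most firsts, then most seconds)
is *not* equivalent: on the shipped coefficient table it would invert the
top two components, contradicting the per-rank reading that generated the
counts. Components that never place are reported with zero counts, not
guessed ranks.

## Synthetic data: what it emulates and what it does not

The land-cover generator is a modified-random-clusters neutral landscape:
cells are marked i.i.d. with probability proportional to the aggregation
parameter (scaled by the 4-neighbor site-percolation threshold 0.5927),
marked cells form 4-connected clusters, unmarked cells join their nearest
cluster, and whole patches are assigned to classes greedily against the
configured area quotas. This gives independent control of class proportion
(realized fractions converge to targets as the grid grows) and spatial
aggregation (clumpiness increases monotonically in the aggregation knob),
which is exactly what the downstream tests need. Default proportions
describe a forest-dominated mosaic (52% forest, 23% agriculture, 13%
developed, 12% other) loosely patterned on mid-Atlantic US land cover, with
aggregation 0.6.

Elevation is a smooth Gaussian random field; population and housing
densities are background levels (2 people/km², one household per 2.4
people) plus smoothed development intensity scaled to 2,500 people/km²
under solid high-intensity cover, with multiplicative lognormal noise.
Counts are Poisson with log-mean = intercept (default ln 2 birds per
count) + the species' true standardized landscape effects at its true
scale + small additive survey terms (observer effects drawn once per
observer from N(0, 0.1); start-time and date effects −0.05 per sd; habitat
offsets ±0.1; land-use-change −0.1), mirroring covariate adjustment rather
than a detectability model. All randomness flows from one top-level seed
through named substreams (landcover / surfaces / locations / counts), so
identical configurations are bit-identical.

Real landscapes are not neutral: roads, river valleys, and zoning produce
anisotropy and long-range structure the generator lacks; census densities
live on polygons, not smoothed rasters; real counts are zero-inflated and
overdispersed by detectability and behaviour. Passing recovery tests on
this generator therefore demonstrates that the *estimators* are correct
and well calibrated under their assumed data-generating process, not that
any field dataset satisfies those assumptions.

## Validation experiments and problem sizes

The seeded experiments (`forestscape.experiments`) use sizes chosen for
tight statistical margins at interactive runtimes: 100 random 20×20
rasters for exact oracle agreement; n = 5000 for the single
effect-recovery fit (true standardized effects 0.34 and −0.22, unit
noise) and 200 replicates of n = 1000 for CI coverage; 100 replicates of
250 locations on a simulated landscape for scale-of-effect recovery
(effects 0.5/−0.3 at 1 km among radii 0.5/1/2 km); and 60 species (20 per
guild, landscape effects ±1.2 or 0) at 2000 locations with 999
permutations for guild recovery. Determinism is checked by running a small
full pipeline twice and comparing every output byte-for-byte.

## Known limitations

* No spatial autocorrelation modelling: locations are treated as
  independent in the models, as in the covariate-adjustment analyses this
  package supports.
* Gaussian models on transformed counts, not count likelihoods; the
  zero-safe negative inverse differs from a strict `−1/y` for small y.
* The clumpiness tally omits the extreme-proportion boundary correction;
  values at very small class proportions differ slightly from
  implementations that include it.
* Raster I/O is plain-text ASCII grid with a JSON legend sidecar; large
  production rasters are better stored in compressed formats and converted
  on ingest.
* Guild labels depend on the configured scales and the majority-vote
  aggregation; species near the significance boundary can flip labels
  between runs with different permutation seeds.
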