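# Methods

This note documents the models implemented in `pollinet`, the assumptions of
the synthetic-community generator, and the numerical choices that affect
results.

## Data model and conventions

A site community is a bipartite count matrix with rows = plants and columns
= floral visitors; the orientation is fixed and every module assumes it.
Plants carry an origin (`native`/`alien`) and an open-flower count; visitors
carry no origin. Plants that flowered but were never visited (and visitors
never observed) are retained in the community record but dropped, with a
warning, before any network metric is computed: a zero row or column carries
no interactions and would otherwise make overlap- and entropy-based indices
ill-defined.

Flower counts for species with numerous small flowers are estimated as
(mean flowers per inflorescence) × (number of inflorescences), rounded
half-up to an integer. Visitation rate is visits · flower⁻¹ · period⁻¹ with
the period defaulting to one 15-minute plot-day (three 5-minute observation
rounds), configurable because rates are sometimes reported per minute.
Plants with no recorded flowers get a missing rate, never an infinite one.

## Network-level metrics

**NODF** follows the standard paired-overlap definition on the binarized
matrix: for each pair of rows (columns) with *strictly* decreasing marginal
totals, the overlap is the percentage of the poorer species' presences
shared with the richer; ties and empty poorer species contribute zero, and
the index is the grand mean over all row and column pairs (0–100). Counts
are binarized because NODF is a presence–absence concept; H2′ and modularity
use the weights.

**H2′** standardizes the two-dimensional Shannon entropy
`H2 = −Σ p_ij ln p_ij` between the extreme entropies achievable by
nonnegative *integer* matrices with the observed marginal totals:
`H2' = (H2max − H2)/(H2max − H2min)`, clamped to [0, 1] (0 when the extremes
coincide, e.g. a single cell). The extremes are found heuristically:

* *H2min* — greedy specialist packing: repeatedly allocate
  `min(remaining row, remaining column)` to the pair of largest remaining
  marginals, concentrating mass;
* *H2max* — proportional allocation `k_i d_j / m`, floored, with the
  leftover units assigned one by one to the largest-remainder cell whose row
  and column are still short.

Both constructions yield feasible matrices, so the heuristic extremes always
lie inside the exact (exhaustive-enumeration) bounds; the test suite checks
this on every small matrix (≤ 12 cells, marginal totals ≤ 8) where
enumeration is affordable. H2′ is only *approximately* invariant to uniform
count scaling: scaling the marginals by an integer genuinely changes the
achievable entropy extremes (with marginals all 1 only permutation matrices
exist; with marginals all 3 more even fillings appear), so exact scale
invariance is not a property of the index and is tested as stability, not
identity.

**Barber modularity** of a partition g is
`Q = (1/m) Σ_{i,j} (A_ij − k_i d_j/m) [g_i = g_j]` over plant–visitor pairs.
The search is simulated annealing over partitions with three move kinds
(single-species reassignment to an existing or fresh module, 80%; merge of
two modules, 10%; random split of a module, 10%). The initial temperature is
calibrated from sampled uphill deltas so roughly 80% of worsening moves are
accepted; cooling is geometric (0.95), with 50·(r+c) moves per temperature,
stopping after 20 improvement-free temperatures, 3 restarts by default (all
configurable). If no partition beats a single module the single-module
partition (Q = 0) is returned, so the reported optimum is never negative.
On every ≤ 8-species instance in the test set the annealer matches the
exhaustive optimum over all set partitions.

**Robustness** removes one guild (plants by default; visitors by flag) in
random order; a species of the other guild goes secondarily extinct when its
last partner disappears. The survival curve runs over x = fraction removed
with endpoints (0, 1) and (1, 0) included, is averaged over `n_orders`
random orders, and R is its trapezoidal area. The Monte-Carlo estimate
converges to the exhaustive all-orders mean (checked at 2000 orders,
tolerance 0.01, on ≤ 5-plant matrices). The extinction rule is pure
secondary extinction: no reallocation ("rewiring") of interaction weights is
modelled, because the standard implementation of this routine implements
only the survival rule, whatever the surrounding terminology suggests.

## Null models

The CE (degree-proportional) null assigns each cell an independent Bernoulli
presence probability `p_ij = (k_i/c + d_j/r)/2` from the binarized degrees.
One implementation serves both the nestedness and the modularity test (the
two historical tools label the same formula differently). Draws with an
empty row or column are redrawn up to a cap (100 attempts) and then kept
with a logged flag — rejection keeps the null faithful to the Bernoulli
definition while avoiding degenerate metric inputs; the unconditional
expected fill equals Σ p_ij. Significance is one-sided (structure = larger
NODF or Q): p = fraction of null values ≥ observed; z = (obs − mean)/sd,
reported as 0 when the null is constant at the observed value and missing
when the null sd is 0 otherwise. Defaults: 1000 replicates for NODF, 100
for modularity.

## Species-level metrics

Normalized degree is realized partners over possible partners. Strength of
plant i is `Σ_j a_ij / A_j` over visitor column totals — each visitor's
dependency on that plant — so plant strengths sum exactly to the number of
visitor species with visits (a conservation law the suite tests on random
matrices). The nestedness contribution of a species is the z-score of the
observed NODF against NODF values obtained by resampling *only* that
species' presence vector from its CE probabilities, all else fixed
(100 randomizations by default). The CE-based focal null was chosen for
consistency with the network-level null model; the contribution is missing
when the focal null sd is zero.

## Floral traits

Gower distance over mixed traits: quantitative traits contribute
`|x − y| / range` (community-level range), categorical traits a 0/1
mismatch; zero-range traits and missing values drop out of the mean. The
per-species similarity index is `s_i = 1 − mean_{j≠i} d(i, j)` — the only
reading of "1 minus average pairwise distance" under which the index grows
with phenotypic similarity. Chromatic coordinates enter Gower as two
ordinary quantitative traits.

Colour-hexagon coordinates: per receptor channel (UV, blue, green) the
quantum catch of the stimulus is taken relative to the background catch
(von Kries adaptation), receptor excitation is `E = q/(q+1)`, and
`X = (√3/2)(E_G − E_UV)`, `Y = E_B − (E_UV + E_G)/2`. A stimulus equal to
the background maps to (0, 0) and the coordinates are invariant to uniform
illuminant scaling. Receptor sensitivity curves, illuminant and background
are caller-supplied inputs on a common wavelength grid (300–700 nm is the
conventional span); no spectral-file parsing is included.

## Extinction scenarios and effect sizes

Removal counts for `natives_removed` and `random_removal` equal the site's
number of alien plants, so all three scenarios are matched in removal size.
Native/random removal sets are uniform random (abundance-weighted sampling
would be a different hypothesis; the uniform choice matches "randomly
excluded"). Visitors orphaned by a removal are dropped before metrics are
recomputed, consistent with the secondary-extinction rule. Stochastic
scenarios default to 100 replicates with per-replicate values retained;
single-run mode is available.

Effect sizes are bias-corrected Hedges' g:
`SD_pooled = √(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2))`,
`J = 1 − 3/(4(n1+n2) − 9)`, `g = J (M1 − M2)/SD_pooled`, with a normal
approximation CI (`SE² = (n1+n2)/(n1 n2) + g²/(2(n1+n2−2))`). Because a
"percent change according to an effect size" is ambiguous, the arithmetic
percent change `100 (M_scenario − M_intact)/M_intact` is always reported
alongside g rather than folded into it.

## The synthetic-community generator

The generator is a statistical stand-in for the motivating survey, not an
estimator fitted to it. Its defaults are the study conditions: 9 sites,
8–17 plants and 22–38 visitors per site, alien species proportion
0.22–0.50, per-site alien flower share spanning 0.11–0.99 across a study,
504–3335 visits per site, and one super-generalist visitor whose expected
visit share is 0.575.

Mechanics per site (one substream per site index from the master seed; no
global random state):

* flower abundances are lognormal (log-sd 1.5); alien abundances are then
  rescaled multiplicatively so the alien flower share hits the site target
  (setting the target to `None` skips the rescaling and makes abundance
  origin-blind);
* each plant gets five traits (flower height, corolla diameter, corolla
  opening — zero for the non-tubular half — and two chromatic coordinates).
  Morphological traits are lognormal (log-sd 2.5) and chromatic coordinates
  signed-lognormal around the achromatic centre: right-skewed,
  outlier-ranged distributions are what makes community Gower similarity
  land near the observed ~0.79 (mean ≈ 0.76 across default sites, within
  the 0.7–0.9 band); symmetric light-tailed traits would push it to ~0.65.
  δ > 0 shifts alien trait means in units of the trait spread; δ = 0 draws
  both origins from one distribution;
* visitors get lognormal activity levels and a latent preference point in
  trait space; interaction propensity is
  `p_ij ∝ flowers_i^α · activity_j^β · exp(−γ · mismatch_ij)` with α = 0.5,
  β = 1, γ = 1 by default. The mismatch is the Gower distance on *jointly
  rank-transformed* traits — ranking removes the outlier dominance of the
  raw ranges, which would otherwise collapse the mismatch into separable
  row/column effects and neutralize γ. γ = 0 gives the rank-one,
  abundance-driven (nested) regime; large γ carves trait-matched modules
  and lowers NODF. `alien_gamma` can relax matching for aliens only, which
  plants a detectable "aliens are super-generalists" signal;
* the super-generalist visitor ignores trait matching and its propensity
  column is scaled so its expected visit share equals the configured value;
* all visits are drawn as a single multinomial of the site total, so totals
  match the configured range exactly; each cell's visits are then spread
  multinomially over nine survey days to produce the visit-event log used
  by the completeness module.

α = 0.5 makes expected visits grow sublinearly with flower abundance, so
visitor richness rises with abundance while the per-flower visitation rate
falls (log–log slope ≈ −0.5) — the qualitative abundance–rate relation seen
in the field data, whose fitted slope was steeper; the generator reproduces
the sign, not the magnitude.

What the generator does *not* emulate: day-to-day variance in visit totals
(the site total is one draw), phylogenetic or spatial structure in traits,
visitor abundance dynamics, and sampling error in flower counts. Passing
tests therefore show the pipeline recovers planted statistical structure of
this kind; they are not evidence about any particular field system.

## Sampling completeness

The sampling unit is a site-day. Accumulation curves are means ± sd over 500
random sample orderings (without replacement). Chao1 is
`S_obs + F1²/(2 F2)` and switches to the bias-corrected
`S_obs + F1(F1−1)/(2(F2+1))` when there are no doubletons (the convention of
the usual estimation software); both variants are retrievable, and
completeness is `100 · S_obs / Chao1`.

## Problem sizes and defaults used in checks

The bundled checks run the generator at its default (study-condition) sizes:
200 sites for the alien-flower-share and super-generalist recovery, 100
sites for the origin-blind scenario-equivalence check (robustness at 50
removal orders there), 50 sites for the γ-monotonicity, trait-similarity
and planted-generalist checks. Exhaustive oracles run on ≤ 12-cell matrices
(H2 extremes), ≤ 8-species networks (modularity) and ≤ 5-plant matrices
(robustness, 2000 Monte-Carlo orders). The full-pipeline tests use reduced
replicate counts (a few nulls and scenario replicates) since they exercise
plumbing, not statistics.

## Known limitations

* The H2 extreme-entropy heuristics are not guaranteed optimal on large
  matrices; they are exact-bounded only where enumeration is feasible.
* Simulated annealing is stochastic; equality with the exhaustive optimum
  is established on small instances, while large networks get a
  best-found-partition guarantee only (Q ≥ 0 always).
* The robustness routine models secondary extinction without interaction
  rewiring; systems with flexible foragers will be more robust than R
  suggests.
* The CE null conditions on degrees only; fixed-marginal (swap/curveball)
  and weighted (Patefield) nulls are out of scope.
* Scenario inference across sites (mixed models on scenario outputs) is
  left to general-purpose statistics packages.
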