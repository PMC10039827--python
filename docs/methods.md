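# Methods

`agrisem` implements confirmatory path analysis (piecewise structural
equation modelling) for site-level landscape data: the question it answers
is how much of the effect of agricultural land cover on bird guild
richness is direct, and how much is routed indirectly through the natural
land covers that agriculture displaces.

## The model

A study design is a directed acyclic graph (DAG). Nodes are site-level
variables: agricultural covers (proportion cropland, proportion perennial
forages and grassland, mean field size), natural covers (proportion
forest, shrubland, hedgerow; forest edge length) and one richness count
per guild. A link `u -> v` asserts a causal effect of `u` on `v`.
Richness nodes are sinks (counts cause nothing in the diagram) and are
modelled as Poisson with a log link; every other node is Gaussian.

The diagram is fitted *piecewise*: one local regression per endogenous
node, with its diagram parents as predictors. All covariates are
standardised (sample SD, n−1) before fitting; richness counts are left
raw. One link — forest → forest edge — is quadratic, because edge amount
peaks at intermediate forest cover; the pair {x, x²} enters and leaves
candidate models together, the square of the standardised covariate is
not re-standardised, and the link's single path coefficient is the sum of
the linear and quadratic estimates.

### d-separation test

The diagram's testable content is its basis set: one conditional
independence claim per unordered non-adjacent pair of nodes. We use the
union basis set: the claim's response is the topologically later member,
and the conditioning set is the union of the direct parents of both
members (the standard construction for this test; a pair of parentless
nodes yields a marginal claim). Each claim is tested by regressing the
later member on conditioning set plus earlier member, in the later
member's family, and taking the two-sided Wald p-value of the earlier
member's coefficient. Gaussian claims use the exact t reference on the
residual degrees of freedom (this is what `lm`-based workflows report and
it makes null p-values exactly uniform); Poisson claims use the
large-sample normal reference.

The k p-values combine into Fisher's C = −2 Σ ln p_i, referred to χ² with
2k degrees of freedom; a small upper-tail probability rejects the
diagram. An empty basis set (saturated diagram) gives C = 0, p = 1. A
claim p-value of exactly 0 raises rather than silently producing an
infinite C; an explicit floor can be configured.

Claims failing at α (default 0.05, configurable) earn an added linear
link oriented from the claim's earlier to its later member — this
preserves acyclicity and the land-cover-causes-richness reading — and the
test is re-run on the revised diagram. One revision round is the default
(matching the single-revision workflow the method is normally reported
with); `iterate` repeats until no claim fails. No multiplicity correction
is applied to claim p-values.

### Path coefficients and model selection

Every endogenous node gets an all-subsets AICc model selection: the
global model with all diagram parents, the intercept-only null, and every
sub-model (quadratic pairs moving together). AICc = −2ℓ + 2K +
2K(K+1)/(n−K−1), where K counts intercept and slopes plus, for Gaussian
fits, the error variance — so AICc is a consistent likelihood-based
quantity across families. Ties prefer fewer parameters, then
lexicographic term order. Predictors in the lowest-AICc model have
*strong* support; predictors absent from the top model but present in
some model within 2 AICc units have *weak* support.

The coefficient placed on a diagram link (used in path products and edge
labels) is the top-model estimate for strong predictors, the estimate
from the best-ranked window model containing the predictor for weak ones,
and 0 otherwise. This rule is deterministic and reproduces the practice
of drawing both thick (strong) and thin (weak) links with estimates.

Gaussian models are fitted by ordinary least squares (normal equations);
Poisson models by iteratively reweighted least squares started at
intercept ln(mean + 0.5) with zero slopes, converged when the relative
deviance change falls below 1e−10 (100 iterations maximum). Rank-deficient
designs, zero-variance inputs and all-zero counts raise immediately.

### Effect decomposition

For each agriculture variable and each guild: the direct effect is the
coefficient of the direct link to richness (0 if absent); each indirect
pathway contributes the product of its link coefficients; the indirect
effect is their sum and the total is direct + indirect. The proportional
change |total|/|direct| (1 decimal, half away from zero) is labelled
"more"/"less" (ratio ≥ 1 or < 1) with the sign of the total. Reported
effects are rounded to 3 decimals.

A caveat reproduced deliberately: richness links carry log-scale Poisson
coefficients while upstream links are identity-scale, so pathway products
mix scales. The decomposition is a path-diagram summary, not a marginal
effect on the count scale; for a fully Gaussian linear system it equals
the +1 SD do-intervention response exactly (verified in tests to 1e−10).

### Spatial screen

Before interpretation, each guild's richness is screened for spatial
autocorrelation with Moran's I (row-standardised inverse-distance
weights, 999 permutations, two-sided p as twice the smaller tail with the
+1 correction; k-nearest-neighbour weights are available). The weight
scheme and test flavour are defensible defaults rather than uniquely
determined choices; any reasonable pair reproduces "no autocorrelation"
on well-mixed data.

## Guild diagrams

Three diagram pairs (a-priori and revised) ship with the package, one per
guild. Their node sets are the package's own encoding choice, constrained
jointly by the hypothesised link table, by the list of links added after
failed independence claims, and by the published indirect-pathway counts
per guild × agriculture variable (5, 15, 7, 5, 1), which the shipped
revised diagrams reproduce exactly:

- **forest**: cropland, mean field size, forest, hedgerow, forest edge,
  richness (perennial forages/grassland and shrubland omitted);
  forest-edge → richness included.
- **shrub-edge**: cropland, perennial forages/grassland, forest,
  shrubland, hedgerow, forest edge, richness (mean field size omitted);
  a direct perennial-forages → richness link is encoded a-priori, since a
  direct effect is reported for it.
- **open country**: cropland, perennial forages/grassland, mean field
  size, hedgerow, forest edge, richness (forest and shrubland omitted);
  forest-edge → richness (negative) included.

Added links in the revised versions: cropland → {hedgerow, forest edge,
richness} for all guilds, plus perennial forages → {hedgerow, forest
edge}, forest → shrubland and shrubland → forest edge for the shrub-edge
guild.

## Synthetic data

The generator draws site tables from the structural equations of a
diagram. Defaults are the study conditions the analysis targets: 127
survey sites, correlated agriculture–forest gradients, Poisson richness.
Exogenous nodes are standard normal. For each endogenous Gaussian node
the residual variance is solved analytically so the node's marginal
variance is 1 (covariances propagate through the linear system; a
quadratic term of a unit Gaussian parent contributes variance 2β² and
zero covariance with linear terms). Structural coefficients are then
directly comparable to the standardised-scale estimates the pipeline
produces, which is what makes the recovery checks interpretable.

Default truth per guild: moderate effects, |β| between 0.25 and 0.6, in
the hypothesised directions; the quadratic forest → forest-edge pair is
(0.3, −0.25). Richness intercepts are ln-scale: 1.95 for forest and
shrub-edge (about 7 species per site) and 0.3 for open country (about
1–2 species per site), matching the reported per-site means. A Poisson
linear predictor beyond ±20 raises instead of overflowing.

What the generator does *not* emulate: bounded compositional covariates
(proportions summing to ≤ 1), detection error in the richness counts,
spatial dependence among sites, and real parcel geometry. Tests passing
on this generator therefore validate the statistical machinery under the
model's own assumptions, not robustness to their violation.

The raster pathway supplies bounded compositions when needed: a
patch-growing process fills exact cell quotas per class on a 33×33 grid
of 30 m cells (1 km²), hedgerows are one-cell-wide strips preferring
field boundaries. Metrics mirror the field rules: mean field size over
4-connected agricultural components (cropland + forage/grassland) after
removing components under 1 ha (≥ 12 cells at 30 m — the raster analogue
of a vector parcel filter, hence approximate); forest edge as the count
of interior forest/non-forest cell faces × 30 m, with map-border faces
excluded (edge is measured within the landscape, not against its frame).
Hedgerow digitisation rules (width < 30 m, canopy gaps ≤ 12 m, length
≥ 24 m) exist only as generator constraints, not as re-measured imagery
rules.

## Numerical and design choices

- Wald (not likelihood-ratio) claim tests: deterministic and cheap; the
  exact-t Gaussian version is uniformly distributed under the null.
- Added links are always linear with no predicted sign.
- AICc requires n > K + 1 and raises otherwise.
- Decomposition of an unreachable response returns an all-zero record
  with an empty path list; a zero direct effect leaves the proportional
  change undefined rather than infinite.
- Reports are written with sorted keys and are byte-identical across runs
  at fixed config and seed.

## Problem sizes used in the checks

Replicated checks run at the sizes the analysis is designed for: 127
sites for recovery (200 replicates per guild in the test suite, 60 in the
acceptance script), 500 sites × 100–200 replicates for d-separation
calibration, n = 5000 single replicates for large-sample sign recovery.

## Known limitations

- Mixed identity/log path products (above) — reproduced, not corrected.
- No overdispersion handling (quasi-Poisson/negative binomial), no mixed
  models, no model averaging, no interaction terms.
- No standard errors or bootstrap intervals for indirect and total
  effects.
- The union basis set conditions on diagram parents only; claims about a
  richness response therefore condition on its diagram parents, not on
  every upstream covariate.
- Latent variables, feedback loops and undirected correlational links are
  out of scope by construction.
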