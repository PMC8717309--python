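# Methods

`harelink` re-implements, as a tested pipeline, the analysis of a controlled
endozoochory study: seeds of 44 arable plant species were fed to captive
European brown hares (*Lepus europaeus*), seedlings emerging from feces were
counted against each species' control germination capacity, the influence of
seed morphology on gut-passage survival was modelled while controlling for
phylogenetic relatedness, and GPS tracking quantified how many habitat
patches a hare can connect within its seed retention time. This note records
the models, the numerical choices, and what the synthetic data do and do not
emulate.

## Seed traits and standardized germination success

For a seed of length *l*, width *w*, height *h* (mm), mass *m* and volume
*V*:

- eccentricity index EI = *l*/*w* (elongation; 1 for an equant seed);
- flatness index FI = (*l* + *w*)/(2*h*);
- density = *m*/*V* (units as supplied, mg/mm³ in the packaged table;
  mass units are treated as opaque and never converted);
- shape variance Vs = population variance of (1, *w*/*l*, *h*/*l*)
  (0 for a sphere);
- surface area: ellipsoid approximation for compact seeds, cylinder
  (2πr² + 2πr*l*, r = (*w* + *h*)/4 by default, configurable to *w*/2) for
  slender ones, switched on Vs against `vs_threshold`.

The threshold default is 1.0, the value the branch rule is conventionally
quoted with — but Vs ≤ 2/9 whenever length is the longest dimension, so at
that default the cylinder branch is unreachable and the package emits a
warning (once per process). A threshold of ~0.1 makes the branch active.
The ellipsoid formula is the Thomsen approximation (p = 1.6075), accurate to
about 1% for realistic seed shapes; an exact numerical-quadrature option
exists and the branch and method taken are recorded in the result.

Standardized germination success expresses feces germination relative to the
number of germinable seeds fed:

    SGS [%] = 100 · feces_seedlings / (capacity/100 · seeds_fed)

It can exceed 100% (one low-capacity species in the packaged data reaches
219%). Species with zero control capacity have no defined SGS; they are
excluded from modelling but can be counted as SGS = 0 in group summaries
(`na_policy="zero"`), the convention under which the packaged table's group
means reproduce their published values exactly after 2-decimal rounding.

### The packaged experiment table

The per-species table ships with the package (`harelink.datasets`). Raw seed
dimensions live in unpublished supplementary material, so the table carries
the published derived indices; the formula paths from raw dimensions are
exercised against synthetic dimensions instead. Per-species seedling counts
are likewise not published but are uniquely determined by inverting the SGS
formula; the inferred integers sum to the experiment's reported 177
seedlings of 34,710 seeds fed (0.51%). The `sgs` column holds the published
2-decimal values (the precision at which downstream means were reported);
`sgs_recomputed` carries the full-precision forward recomputation, and the
two agree within half a printed unit everywhere.

### Predictor screening

Candidate predictors (density, EI, area, FI, mass, volume, area/mass) are
screened pairwise by Pearson correlation on log values; for each pair with
|r| above the threshold (default 0.7) the lower-priority member is dropped,
scanning greedily in priority order (default: density, EI, area first). On
the packaged table this drops FI, mass and volume (all correlated > 0.8 with
area) and retains density, EI and area — plus area/mass, whose largest
correlation with any other predictor is 0.67 and which therefore survives a
0.7 screen on these data; the model stage uses {density, EI, area}. An
exploratory PCA (correlation-matrix eigendecomposition) is reported for
variable choice only.

## Phylogenetic mixed model

For n species with response y = log(SGS + 1) and design matrix X
(intercept + log predictors):

    y = Xb + a + e,  a ~ N(0, σ²ₚ R),  e ~ N(0, σ²ₑ I)

R is the phylogenetic correlation matrix: shared root-to-tip path lengths
C from the newick tree, standardized to unit diagonal (the appropriate form
for non-ultrametric trees with substitution-scale branch lengths; raw C is
also available). Zero-length terminal branches receive an epsilon (1e-8 of
tree depth) on the diagonal to keep C invertible. Tip labels are matched to
species names case-insensitively with spaces/underscores unified; anything
unmatched is an error, never fuzzy-matched.

Lynch's phylogenetic heritability h² = σ²ₚ/(σ²ₚ + σ²ₑ) is computed per
posterior draw and summarized by its mean and 95% highest-posterior-density
interval (narrowest window over sorted draws). The no-phylogeny model
reports h² = 0 by construction.

### Sampler

Blocked Gibbs in the eigenbasis of R (R = UΛUᵀ), where every conditional is
diagonal:

- **b** is drawn with the random effect integrated out analytically,
  b | σ² ~ N(b̂, (XᵀV⁻¹X)⁻¹) with V = σ²ₚR + σ²ₑI and a flat prior — a
  block update that avoids the slow b–a random walk on small n;
- **a** | b, σ² as independent normals in the eigenbasis;
- variances by conjugate inverse-gamma updates, IG(0.001, 0.001) by default.

A parameter-expanded option (`variance_prior="px"`) rescales the random
effect through a working parameter α ~ N(0, 1) with σ̃² ~ IG(ν/2, ν/2),
ν = 1, giving a half-Cauchy-type prior on σₚ. The inverse-gamma shape piles
prior mass at zero variance and visibly understates h² when the likelihood
is weak; the PX prior is the recommended (and internally used) setting for
heritability estimation, and simulation coverage below is reported under it.
Chains are deterministic given the seed; split-half R-hat and effective
sample sizes (via arviz) are attached to every fit.

Default chain settings are desk scale (50,000 iterations, 5,000 burn-in,
thin 10 — seconds per fit at n ≈ 100); production-scale settings in the
millions of iterations are expressible through `ModelSpec` but numerically
unnecessary for this conjugate sampler, whose retained draws are already
near-independent (ESS close to the draw count).

### Model comparison

DIC uses the **marginal** Gaussian deviance, y ~ N(Xb, σ²ₚR + σ²ₑI), with
random effects integrated out: D̄ + pD, pD = D̄ − D(posterior means). The
marginal deviance keeps pD stable on small n; software that uses the
conditional deviance (e.g. MCMCglmm) will give numerically different DIC
values, so published DIC differences are treated as qualitative anchors
only. All predictor subsets (including intercept-only) are enumerated and
ranked; models within 2 DIC units of the best are flagged as competing;
ties break by parameter count, then lexicographic predictor order.

## Movement and connectivity

Tracks are hourly GPS fixes in a projected planar frame (meters;
degree-range coordinates are rejected rather than silently reprojected).
Raw fixes are resampled to one per whole hour (nearest fix within ±10 min;
gaps are preserved, never interpolated). Each fix is assigned a land-use
patch by point-in-polygon with an inclusive boundary (ties to the
lexicographically smallest patch id); fixes outside all patches are
"matrix", excluded from connectivity counts but retained for travel
distances.

Retention windows are 5.6, 7 and 8.4 h (mean gut retention ± its
confidence bound). A window starting at fix t₀ contains the maximal run of
consecutive fixes in the **closed** interval [t₀, t₀ + T] — with hourly
fixes a 5.6 h window holds up to 6 fixes and a 7 h window up to 8; the
fractional durations cannot align with an hourly grid and the closed
interval is the documented resolution. Windows are truncated at gaps larger
than 1.5× the nominal fix interval. The window slides one fix at a time to
the end of the track. Per window the package counts distinct land-use types
and unique patches per type, and sums consecutive-step path length
(net displacement is available by option; "distance traveled" is read as
cumulative path, consistent with step-based movement tooling).

Per-individual means over windows are aggregated across individuals
(mean ± SD) per retention time; individuals tracked under 10 days are
excluded and listed. "Connections" are operationalized as consecutive-fix
transitions between different patches (self-transitions excluded),
classified by unordered land-use pair and reported as percentages — one
reasonable reading of an operation the source analysis leaves undefined,
so real-data composition percentages are not comparison targets. Centroid
distance matrices of visited patches are summarized by pair class
(differing types, field–field, grassland–grassland, forest–forest).

## Synthetic data

Generators exist so every stage is testable without the original field
data; all are deterministic under a single integer seed.

- **Trees**: pure-birth (Yule) with exponential waiting times; ultrametric;
  expected depth (1/λ)Σₖ₌₂ⁿ 1/k, verified by Monte Carlo.
- **Traits**: Brownian motion on the log scale along the tree
  (tip covariance = rate × shared path length), exponentiated; root values
  match the magnitudes of the real density/EI/area columns. With
  `phylo_signal=False` log traits are iid with matched marginal variance.
  Tree-structured covariates overlap the few deep-split eigendirections of
  R that identify σ²ₚ, so heritability recovery studies use the
  signal-free option to keep all phylogenetic structure in the random
  effect.
- **Germination**: the inverse of the fitted model — η = Xb + a + e with
  phylogenetically correlated a, SGS = max(exp(η) − 1, 0), discretized to
  integer seedling counts (nearest consistent integer by default; a
  binomial option provides a deliberate misspecification stress test). The
  default intercept (7.2) offsets the trait scales so η sits well above the
  zero floor and below the count ceiling: the generator then stays within
  the model family it inverts, which parameter recovery requires. Real
  data occupy a near-zero, heavily censored regime; lowering the intercept
  reproduces it, at the cost of deliberate misspecification.
- **Landscapes**: jittered rectangular grids tiling the extent exactly
  (mean patch area = extent/cells; jitter 35% of a cell), land-use types
  drawn from configurable proportions (default ≈ 2/3 arable with
  grassland, forest and minor types). The study contrast is ~27.5 ha
  ("simple") vs ~2.9 ha ("complex") mean patch size.
- **Tracks**: hourly correlated random walks — gamma step lengths (default
  shape 1.5, scale 100 m, mean 150 m/h, between the ~110 and ~185 m/h the
  two real landscapes imply), wrapped-Cauchy turning angles (concentration
  0.5), reflection at the extent border, optional soft attraction to
  grassland.

What the generators do **not** emulate: behavioral states and diel rhythm,
GPS error, home-range fidelity, real land-cover geometry, seed-intake
variation among hares, and the deep censoring of real germination counts.
Passing recovery tests therefore demonstrate correctness of the estimators
under their assumed model, not field realism.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds through numpy
  Generators; identical seed + configuration gives bit-identical output.
- Non-positive dimensions, masses, volumes and log arguments are errors
  naming the offending quantity/species, never silently dropped; missing
  heights are flagged, never imputed.
- R must be numerically positive definite (minimum eigenvalue > 1e-10);
  failures instruct the caller rather than regularizing silently.
- Draws with singular marginal covariance are skipped in DIC with a count
  reported; none occur in practice with proper priors.
- HPD intervals use exact sorted-window search; fewer than 100 retained
  draws triggers a warning.
- Empty groups, single-patch distance matrices, all-matrix windows and
  tracks shorter than the retention time produce explicit flagged results,
  not exceptions.

## Known limitations

- The published ITS-based maximum-likelihood tree is not packaged; analysis
  driver 02 uses a clearly labelled synthetic surrogate tree, so its h² and
  DIC values characterize the method, not the published phylogeny.
- The printed endangered/non-endangered group means appear swapped relative
  to recomputation from the packaged table; red-list summaries are reported
  but not asserted against published values.
- DIC with marginal deviance is not numerically comparable to MCMCglmm's
  conditional-deviance DIC; published h² = 0.046 and ΔDIC = 3.8 serve as
  qualitative anchors only (unstated priors, different deviance).
- The collinearity screen retains area/mass on the packaged table (its
  largest correlation is 0.67 < 0.7); the original drop presumably rests on
  unavailable supplementary raw dimensions.
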