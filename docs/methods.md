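# Methods

`netdissim` tests whether large-scale ecological boundaries (ecoregions
nested within biomes) and human-disturbance gradients structure the
composition and architecture of local plant–frugivore interaction networks,
against a background of spatial and elevational distance decay and of
heterogeneous sampling.  Everything is phrased in the currency of pairwise
distance matrices over the set of local networks.

## Network dissimilarity

A local network is a labeled plants × birds matrix of nonnegative
interaction frequencies.  Three response facets are computed per network
pair, all in the Sørensen form βₓ = (b + c)/(2a + b + c) on sets (a shared,
b and c unique to either side); link sets are binarized even for
quantitative networks:

- **β_S** — species turnover over the pooled, guild-tagged species sets
  (a plant and a bird sharing a name never collide);
- **β_WN** — dissimilarity of the whole-network link sets;
- **β_OS (rewiring)** — β_WN restricted to the subwebs induced by shared
  plants × shared birds.  Undefined (and excluded, not zeroed) when a guild
  shares no species or both subwebs are linkless.  β_ST = β_WN − β_OS is
  reported but not modeled.

## Structure metrics and the structural response

Five weighted descriptors per network:

- **weighted connectance** — Bersier-style weighted linkage density over
  species count.  Effective partner numbers use base-2 entropy (2^H);
  configurable.
- **wNODF** — weighted nestedness by overlap and decreasing fill, 0–100.
  We implement the reference semantics used for quantitative webs: rows and
  columns are ranked by decreasing fill (weighted totals break ties) and a
  pair contributes only when fill strictly decreases, the contribution being
  the percentage of the sparser member's positive cells strictly exceeded by
  the denser member.  The suite cross-checks this against R vegan's
  `nestednodf(weighted = TRUE)`.
- **interaction evenness** — Shannon evenness of the cell weights with the
  ln(R×C) ("prod") denominator; a single-cell network is defined as 0.
- **mean PDI** — species-level Paired Difference Index (max-normalized
  flows, zeros padded to the size of the opposite guild), pooled over both
  guilds as an interaction-total-weighted mean.  The weighting variable and
  guild pooling are our choices; per-species values are accessible for
  alternatives.
- **modularity Q** — Barber's bipartite modularity maximized by a seeded
  label-propagation search: per-node reassignment to the best existing or
  fresh module, module-pair agglomeration, iterated to convergence; best of
  40 initializations (singletons first, then random coarse partitions).
  40 restarts is the default search budget because it reproduces the
  exhaustive-search optimum on every random instance up to 6×6 we test
  (1000 seeded draws); the budget is configurable.

The structural response z-scores the five metric columns, runs a PCA, keeps
the leading components reaching a variance target (default 0.85; an exact
component count can be forced for replication), and takes Euclidean
distances between score vectors.

## Predictor distance matrices

- **Boundary (binary)** — 0 for same ecoregion/biome, 1 for distinct.  The
  model codes the indicator as 1 = "same region", so a negative coefficient
  means lower dissimilarity within a region.
- **Boundary (quantitative)** — z-score + PCA of a six-variable regional
  environmental table (temperature, temperature seasonality, rainfall,
  rainfall seasonality, slope, human footprint), Euclidean distance on the
  retained scores, expanded to networks via region membership.  Raster
  extraction is upstream; the package consumes tabular values.
- **Footprint, elevation, sampling hours/months/years/intensity** —
  |difference| of the site values (1-D Euclidean).
- **Spatial** — great-circle (haversine) distance, IUGG mean Earth radius
  6371.0088 km.
- **Methods** — Gower dissimilarity over the four categorical method
  descriptors (0/1 mismatch; range-normalized |diff| would apply to any
  numeric column), then classical-scaling PCoA (4 axes by default, fewer if
  the positive spectrum is smaller) and Euclidean distance on the axes.
  PCoA discards negative eigenvalues without Lingoes/Cailliez correction
  and logs their inertia share.

All matrices are vectorized over the lower triangle in one fixed order
(row-major over sorted network ids), giving n(n−1)/2 aligned rows.

## The GAM-based MRM

The response vector is modeled as Gaussian:

y = α + Σ_k βk·I_k + Σ_m f_m(x_m) + ε,

with 0/1 boundary indicators entering linearly and each quantitative
distance getting a penalized spline smooth.  Smooths use a low-rank 1-D
thin-plate-type basis: radial cubics |x − κ|³ at 10 quantile knots, the
two-dimensional polynomial null space removed by a QR reparameterization
(the linear part stays as an unpenalized column; the constant belongs to
the intercept), columns centered for identifiability.  Basis dimension 10
caps each smooth's EDF at 9.  Smoothing parameters are selected by profiled
Gaussian REML, optimized over log-λ with the analytic gradient (L-BFGS-B,
bounds e⁻¹⁵–e¹⁸).  A ridge of 1e−9 × mean(diag X'X) stabilizes the normal
equations against exact collinearity (study-level covariates are constant
within studies).  The fitter is validated against mgcv (`method="REML"`,
`bs="tp"`) in the suite: parametric estimates agree to ~1e−4 and explained
deviance to <0.01 on a shared dataset.

Term statistics: t = β̂/SE from the Bayesian posterior covariance
(X'X + S_λ)⁻¹σ̂², σ̂² = RSS/(n − EDF_total); smooths get a Wald-type
F = β̂'V⁺β̂/EDF on their coefficient block.  These are *reference* statistics
only — inference is by permutation.

**Permutation inference.**  Because all pairs sharing a network are
dependent, each of n_perm (default 1000) iterations draws a random
relabeling of networks, applies it simultaneously to the rows and columns
of the response matrix only, re-vectorizes and refits.  p = (1 + #{|t*| ≥
|t|})/(n_perm + 1) for parametric terms (two-tailed on the signed
statistic), and upper-tailed on F for smooths (F is nonnegative, so
"two-tailed" has no meaning there).  The +1 convention makes the smallest
attainable p equal to 1/(n_perm+1).  Smoothing is re-estimated on every
refit by default; `fast_perm` freezes λ at the observed fit for speed.
Permutations are pre-drawn from one seeded generator, so results are
reproducible bit-for-bit and invariant to the thread count.

Calibration, measured by the suite on null synthetic data (all generator
mechanisms off, geography randomized; 200 datasets × 199 permutations):
per-term rejection at α = 0.05 falls within 0.02–0.08.  An injected
−0.07 same-ecoregion shift (n = 60 networks, noise SD 0.05) is recovered
with the correct sign in all of 100 replicates and mean bias below 0.01.

**Deviance partitioning.**  Explained deviance is 1 − RSS/TSS (fractions of
total response deviance).  Every reduced model — each subset of the
variables of interest removed — is refitted with the remaining smooths'
λ frozen at the full-model values (re-estimated λ would compensate for a
dropped correlated predictor).  Unique and shared (Venn) components follow
by Möbius inversion over the subset lattice; they sum, exactly, to the
deviance attributable to the variables of interest.  Negative components
(suppression) are retained and flagged, never hidden.  A 2^k guard refuses
more than 5 variables of interest by default.  Note that even genuinely
independent predictors show a shared component of order ±2β₁β₂var(x)/var(y)
× O(n_pairs^−1/2) from chance correlation; it vanishes only asymptotically.

**Jackknife.**  Leave-one-study-out: drop a study, rebuild every distance
matrix on the remaining networks, refit (no permutations), report each
term's t or F.  Reduced datasets below 4 networks are flagged and skipped.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes, not
a mechanistic frugivory model:

- **Landscape** — biomes as latitudinal bands, ecoregions as longitude
  cells within bands, sites uniform inside cells; nesting holds by
  construction.  `randomized` placement shuffles region labels over sites,
  decoupling the boundary term from geography (used for calibration, where
  identifiability matters more than realism).  Elevation follows a
  latitudinal gradient plus noise; footprint is a low/high mixture
  independent of region; studies group geographically proximate sites and
  carry the sampling covariates (hours, months, mean year, intensity, four
  categorical method descriptors).
- **Pools** — every species has a home ecoregion; biome pools include
  foreign species with probability `biome_pool_overlap` (default 0.3) and
  ecoregion pools subsample their biome pool at `ecoregion_pool_overlap`
  (default 0.5).
- **Occupancy** — base rate 0.55 over the ecoregion pool, modified by
  exp(−decay·distance-to-home) (default 2e-4 per km, a ~5000 km e-folding
  consistent with continental-scale distance decay), exp(−boundary_effect)
  for species away from home (default 0.7), and a disturbance filter that
  favors the synanthropic 20% of species at high footprint and suppresses
  the rest.  The three modifiers are renormalized to mean 1 over the pool,
  so they shift *which* species occur rather than site richness — turnover
  mechanisms should not masquerade as richness gradients, and networks stay
  above the ≥3-species-per-guild inclusion floor.
- **Links and weights** — 1-D latent trait matching sets link probability;
  weights are log-normal (σ = 1); a saturating detection process
  1 − exp(−hours/40) thins links by sampling effort.  Invalid draws are
  retried up to 10 times.

Defaults (3 biomes × 4 ecoregions × 5 sites = 60 networks, 10 studies,
pools of 160 plants and 120 birds) give networks of ~20–45 species, i.e.
the size range where all metrics are well defined, while keeping full
pipelines fast.  What the generator does *not* emulate: phenology,
migration, abundance dynamics, taxonomic error, spatially autocorrelated
sampling effort.  Green tests therefore show the *machinery* is correct and
calibrated under the assumed structure, not that real frugivory data meet
those assumptions.

For effect-recovery experiments, a known additive same-ecoregion shift is
injected directly into a synthetic response built over the simulated
landscape (`injected_boundary_response`); the generator's own
`boundary_effect` acts at the occupancy level, and its realized
dissimilarity contrast is recorded in the dataset's ground truth rather
than assumed.

## Numerical choices and degenerate inputs

- Constant predictor terms (e.g. a single-ecoregion dataset) are dropped
  with a warning, never silently imputed.
- Constant metric columns are dropped before PCA; identical profiles give a
  zero structural distance matrix.
- Sørensen on two empty sets, PDI with <2 potential partners, and the
  ratio-of-interactions with an empty catalog are errors/undefined, not 0.
- Ties in permutation statistics count as exceedances (conservative).
- Problem sizes in the suite (200 null datasets at n=30, 100 recovery
  replicates at n=60, 1000 oracle networks up to 6×6) were chosen to give
  per-check Monte-Carlo error well inside the asserted bands.

## Known limitations

- Gaussian response on [0,1] dissimilarities (matching common practice for
  these models); a beta family is a possible extension.
- Raw-response permutation is the implemented scheme; residual-permutation
  variants (Freedman–Lane) are not.
- The rewiring subset is exported with its predictors, but the
  mixed-effects model over that (non-matrix) subset is out of scope.
- PCoA axes beyond the positive spectrum are refused rather than corrected.
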