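# Methods

This note documents the models and procedures implemented in
`rhizotrace`, the defaults that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Imprint quantification

A fluorescence imprint is a gray raster on the convention 0 = black to
256 = white (8- and 16-bit files are rescaled onto this range on read,
with white mapping to 256). Calibration films of known Cd content give
(concentration, mean gray) pairs; concentration is regressed **on** gray
because gray is the measured quantity and concentration the controlled
one, so the fitted map applies to images directly. Two fits are offered:
ordinary least squares (`linear`) and an isotonic
(pool-adjacent-violators) interpolant (`monotone-piecewise`) for
saturating dyes. Both are monotone non-decreasing over the fitted range;
a decreasing linear fit is refused unless an inverted-polarity flag is
passed. Inversion clamps negative concentrations to 0 and flags
extrapolation outside the calibrated gray range.

The **hotspot** statistic marks pixels *strictly* greater than
(1 + f) × mean, f = 0.25 by default. Strictness makes the constant image
unambiguous (0% hotspots), and because the threshold is relative the mask
is invariant under positive rescaling of the raster. The statistic can be
computed on gray (default) or on the calibrated concentration map.

**Colocalization** between the root mask and a level map is a Mantel
test: both rasters are cut into `block`×`block` tiles (default 8 px,
edges cropped to whole tiles; at least 10 tiles required), each tile
summarized by (root-pixel fraction, mean level), Euclidean distance
matrices built over tiles, and a Spearman Mantel correlation tested by
joint row/column permutation with the add-one rule. The tiling
granularity is a genuine free parameter of this construction; it is
exposed on the CLI and its default keeps permutation testing cheap.

Pseudocolor rendering uses a diverging blue→red map with hotspot pixels
overwritten in pure red (255, 0, 0), a color the map itself never emits,
so red pixels in the output count hotspots exactly.

## Community statistics

Alpha indices follow the textbook forms: Shannon −Σp ln p, Simpson
1 − Σp², observed richness, and Chao1 S + F₁²/(2F₂) with the
bias-corrected S + F₁(F₁−1)/2 when no doubletons exist. Rarefaction
subsamples without replacement (multivariate hypergeometric draws).
Bray–Curtis is Σ|x−y| / Σ(x+y).

NMDS minimizes Kruskal stress-1 by iterative majorization: at each step
configuration distances are monotonically regressed on the dissimilarity
ranks (isotonic regression), then a Guttman transform moves the
configuration toward the disparities; the best of `n_starts` seeded
random starts is returned. ANOSIM uses R = (r̄_between − r̄_within)/(M/2)
on ranked distances with label-permutation p (exhaustive enumeration is
available at n ≤ 7 and is exact). SIMPER decomposes the Bray–Curtis
numerator per taxon over all between-group pairs; by construction the
contributions sum exactly to the mean between-group dissimilarity. Welch
t-tests run per taxon on relative abundances (raw counts by flag) with
Satterthwaite degrees of freedom and optional Benjamini–Hochberg column.

The biomarker scan is a deliberately simplified LDA effect size: taxa
pass a Kruskal–Wallis screen at `kw_alpha`, then over 30 bootstrap
rounds an effect is scored as log₁₀ of the mean of the raw class-mean
difference and the unit-loading-scaled LDA projection difference
(abundances scaled to 10⁶, the conventional scale for the 2–6 score
range; default threshold 3.5). The subclass / one-against-all grid of
the full published recipe is omitted — the designs this package targets
have no subclass structure — so scores should be compared within this
implementation, not against other tools digit for digit.

## Null-model assembly

βMNTD for a sample pair averages, over both directions, each taxon's
patristic distance to its nearest taxon in the other sample, weighted by
relative abundance (presence/absence by flag). βNTI standardizes the
observed βMNTD against a null that shuffles tip labels across the whole
phylogeny — the standard "taxa.labels" null — keeping abundances intact:
z = (obs − null mean)/null sd, 999 shuffles by default, seeded. If the
null spread is numerically zero (e.g. a perfect star phylogeny, where
every shuffle is equivalent), the pair reports 0 when the observation
equals the constant null and NaN otherwise; NaN pairs are excluded from
process fractions.

RC_bray builds null communities that preserve each sample's richness and
total abundance: taxa drawn without replacement with probability
proportional to regional occupancy, individuals filled in proportion to
regional relative abundance; RC = 2·((#null < obs) + ½(#null = obs))/N − 1.

Classification uses the standard thresholds: βNTI > +2 variable
(heterogeneous) selection, < −2 homogeneous selection; otherwise
RC > +0.95 dispersal limitation, < −0.95 homogenizing dispersal, else
drift. Patristic distances are computed once per table/tree pairing.

## Co-occurrence networks and keystones

Edges are Spearman correlations between taxa (relative abundances, after
an optional prevalence filter) passing |r| ≥ 0.6 and p ≤ 0.05 — the same
screening thresholds used elsewhere in the pipeline; both are flags.
Topology statistics use greedy agglomerative modularity maximization
(deterministic, unlike Louvain) and the package's own power-iteration
eigenvector centrality on the largest component. ARPACK-based
eigensolvers start from a random vector and are not bit-reproducible
run to run, which would break the pipeline's hash-identical-manifest
guarantee, so power iteration (tolerance 1e-10) is used throughout.
PageRank runs on the |r|-weighted graph, damping 0.85; dangling nodes
redistribute uniformly, so isolated taxa end up with essentially
teleport-only mass. Keystones are the union of the top-k (default 9) by
either score; ties break by node label.

## Metabolite coexpression modules

Peak areas are filtered (maximum across samples ≥ 5) and transformed
log₂(x + 1). Adjacency is |Pearson r|^β (Spearman by flag). The soft
threshold β is the smallest power whose connectivity distribution fits a
scale-free line with R² ≥ 0.8 *and* whose mean connectivity stays ≥ 5 —
without the floor, high powers can look scale-free merely by
annihilating the adjacency. Small or strongly block-structured matrices
often never look scale-free at any usable power; the fallback is then
the conventional sample-size default for unsigned networks (9 below 20
samples, 8 below 30, 7 below 40, else 6), with a warning.

TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij);
modules come from average-linkage clustering of 1 − TOM with a static
cut at 0.95 of the maximum merge height (cutting at the root's doorstep
lets unrelated background metabolites ride into modules) and a minimum
module size of 28; smaller clusters go to the grey bucket. A dynamic
hybrid tree cut was deliberately not used: the static cut is simpler,
fully deterministic, and exposed as a parameter. Eigenmetabolites are
unit-norm first principal components of standardized member profiles,
sign-oriented along the module mean; module pairs whose eigenprofiles
correlate ≥ 0.8 merge iteratively (most correlated pair first).
Module–trait association is Pearson r with two-sided p, Bonferroni
over all module × trait cells; hubs are ranked by kME = |cor(profile,
eigenmetabolite)|. The whole chain is free of randomness.

## Multi-omic integration

Spearman screens report all X×Y pairs with a passed flag at |r| > 0.6
(signed by flag) and p < 0.05 or 0.01 depending on the screening
context; both are parameters. The Mantel test correlates lower-triangle
entries with joint row/column permutation (exhaustive at n ≤ 7).

The Boruta-style screen appends a column-shuffled shadow copy of every
feature, fits a random forest (the forest is a consumed numeric
primitive — regressor for numeric targets, classifier otherwise), and
counts rounds in which a real feature's importance exceeds the round's
maximum shadow importance (ShadowMax). Decisions come from a binomial
test of hits against chance at α = 0.05 with a tentative band.
Permutation importances are the default (impurity by flag, cheaper). A
property worth knowing: with few candidate features, the per-dataset
luckiest noise feature can beat ShadowMax persistently — its spurious
correlation with the target is fixed across rounds and its quantile
within the shadow-importance distribution does not shrink with sample
size — so null calibration statements are made for feature sets of
realistic width (tens of candidates), where that one lingering feature
is a small fraction.

The path model is piecewise: every variable is z-scored and each
endogenous node of the user's DAG is fit by one OLS regression on its
parents, giving standardized coefficients, two-sided p and per-equation
R²; indirect effects are products along directed chains and total
effects their sums. Collinear parent blocks (condition number > 1e8) are
refused. No latent-variable covariance SEM (χ², RMSEA) is attempted.

Variance partitioning fits the response on every non-empty subset of up
to three predictor blocks (7 fits) and decomposes R² — adjusted
(Ezekiel) or raw — by inclusion–exclusion into three unique, three
pairwise-shared and one three-way-shared fraction plus residual. In
unadjusted mode the fractions and residual sum to exactly 1; shared
fractions can legitimately be negative (suppression) and are reported
as-is.

## Synthetic data and what passing tests mean

The generators emulate the target study design — four treatments × five
replicates, fixed sequencing depth (default 10,000 reads/sample, chosen
so rarefaction never confounds tests), block-correlated metabolite
modules ((30, r=0.8) × 3 by default), and a standardized linear DAG over
{metabolite, microbe, soil, Cd} whose implied covariance and variance
fractions are computed analytically as ground truth.

* **Imprint**: a connected branching root path from the top edge;
  truth concentration = background 1 mg/kg + exponential root-proximal
  enrichment (amplitude = colocalization strength, decay 8 px) + pixel
  noise; gray is a fixed affine map of concentration into [20, 230], so
  calibration is well-conditioned and clipping rare; films sample the
  same map.
* **Community**: pure-birth (Yule) tree rescaled to height 1; habitat
  optima evolve by Brownian motion (σ = 1) along branches, giving the
  phylogenetic trait signal βNTI assumes. Regional base abundances are
  lognormal(0, 1.5) — a realistically steep rank-abundance curve, needed
  so finite-depth samples show compositional turnover (with a flat curve
  every taxon appears in every sample and βNTI degenerates). Group
  environments sit at quantiles of the realized optima spanning the
  10th–90th percentile; "filtered" sampling weights are base ×
  exp(−strength·(optimum − environment)²), so strength 0 reduces exactly
  to the neutral common-multinomial law.
* **Metabolome**: module members load √r on a shared latent factor; peak
  areas are 2^(2z+10), strictly positive and exactly log-linear after
  the standard transform; module 0's factor (plus noise) is the tied
  trait.
* **Integrated block**: variables generated in topological order as
  standardized linear combinations of parents plus Gaussian noise scaled
  to unit marginal variance.

Each generator draws from an independent substream of the seed, so any
product is reproducible in isolation and identical seeds give
byte-identical serialized outputs.

What passing recovery tests show: the estimators detect what was
planted under Gaussian/multinomial noise with exchangeable samples. What
they do not show: robustness to compositional artifacts of real
sequencing (no spike-ins, no depth variation), PCR/primer bias, LC-MS
batch effects, spatially correlated imprint noise, or phylogenetic
uncertainty — none of which the generators emulate.

## Numerical choices and reproducibility

* All permutation/bootstrap p use the add-one rule (never exactly 0) and
  a user seed; exhaustive enumeration replaces sampling where feasible
  (Mantel/ANOSIM n ≤ 7, βNTI ≤ 8 taxa).
* Power iterations stop at 1e-10; NMDS majorization at stress
  improvement < 1e-7, best of 4 starts.
* βNTI pairs with numerically zero null spread (≤ 1e-10 relative)
  report 0 if the observation matches the null, NaN otherwise.
* Degenerate inputs fail loudly with typed exceptions (all-zero root
  masks, single-taxon metacommunities, constant metabolites, conflicting
  calibration films, cyclic DAGs).
* End-to-end runs (`rhizotrace run`, `pipeline.run_pipeline`) hash every
  output file into a manifest; the demo configuration (60 taxa, 20
  samples, 199 nulls, 96×96 imprint — sizes chosen to keep a full run in
  the tens of seconds) is hash-identical across reruns.

## Known limitations

* The simplified LDA effect size is not numerically interchangeable with
  the full published LEfSe; thresholds carry over in spirit, not digit
  for digit.
* The static tree cut can split one planted module into nested clusters
  when correlations are very heterogeneous; the exposed `cut_height` is
  the remedy.
* RC_bray is O(pairs × nulls) with per-null multinomial draws; tables
  beyond a few hundred samples call for fewer nulls or subsetting.
* The piecewise path model assumes linear effects and no latent
  confounding; it reports no global fit statistic by design.
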