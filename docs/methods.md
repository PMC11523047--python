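# Methods

This note documents the models, numerical conventions, and design choices
behind `habspec`, and what the synthetic-data experiments do and do not
demonstrate.

## Preprocessing

The abundance filter removes singleton OTUs (total count 1 across the
dataset) and OTUs whose dataset-wide relative abundance is strictly below
0.005% (`min_rel_abund = 5e-5`), computed on the grand total *before*
rarefaction.  Rarefaction draws each sample down to a common depth
(default 6000) by a single seeded multivariate-hypergeometric draw
(subsampling without replacement); samples below the depth are dropped
with a logged warning.  Single rarefaction under-represents rare taxa
run-to-run; the seed is exposed and an `n_iterations` averaging mode is
available (default 1).  OTUs left with zero total after rarefaction are
pruned by default (flag `prune_zero_otus`).  Missing Newick branch
lengths are treated as 0 with a warning; tree pruning never alters
patristic distances among retained tips (tested).

## Diversity and niche breadth

Shannon entropy uses natural log.  Faith PD sums the branch lengths of
the minimal subtree connecting the present tips *including the path to
the root* (the common default of the microbial-ecology implementations;
`include_root=False` restricts to the MRCA subtree).  Levins breadth is
computed per OTU over samples within a habitat; `units=` enables a
site-pooled mode.  Group comparisons use the tie-corrected
Kruskal–Wallis H with chi-square p, Dunn pairwise z from mean rank
differences with tie correction and two-sided normal p, and Holm
step-down adjustment.

## Beta structure

Bray–Curtis and binary Jaccard come from scipy's `pdist`; unweighted
UniFrac from scikit-bio (verified against a brute-force branch-tally
oracle, exactly, on small trees).  PCoA is classical scaling with Gower
double-centering; negative eigenvalues are reported, not corrected, and
axis percentages use the positive-eigenvalue sum as denominator.
Eigenvector signs follow a largest-magnitude-loading-positive convention
so ordinations are exactly reproducible.

PERMANOVA uses the McArdle–Anderson partition of squared distances —
pseudo-F = (SS_among/(k−1)) / (SS_within/(n−k)), R² = SS_among/SS_total —
with free label permutation and the add-one p-value convention
(ties counted with ≥).  Pairwise PERMANOVAs subset the matrix per pair
and Holm-adjust.  The dispersion test (betadisper analogue) embeds
samples by PCoA keeping negative-eigenvalue axes as imaginary
coordinates; squared distances to the group centroid subtract the
negative-axis contribution and are clamped at zero; the test statistic is
the one-way ANOVA F of those distances under label permutation.  Group
centroids (not spatial medians) and no small-sample bias adjustment.

## Geographic and environmental predictors

Geodesic distances are computed on the WGS84 ellipsoid with Vincenty's
inverse method (tolerance 1e−12 rad); tests check it against an
independent Karney-algorithm oracle (R `geosphere::distGeo`) to within
1 mm.  Vincenty does not converge for near-antipodal pairs; the sites
analysed here are far from that regime and non-convergence raises an
explicit error.  Samples inherit their site's coordinates, so within-site
geographic distance is exactly zero — this motivates the DDR
zero-distance policy below.

Environmental variables are centre-reduced ((x−x̄)/σ, n−1 denominator);
pairs with |Pearson r| > 0.95 are pruned greedily in column order (the
kept representative is recorded).  PCA is SVD-based on the standardized
matrix; the environmental distance is Euclidean on the first two PC
scores, replicated from sites to samples.  PCNM applies PCoA to the
geographic distance matrix after replacing distances above the truncation
threshold by 4× the threshold; with the default threshold equal to the
maximum distance this modification is a no-op and the basis equals the
plain PCoA eigenvectors, scaled orthonormal.  The pipeline uses the first
three PCNM axes.  Note that with only five sites the site-contrast space
has four dimensions, so three PCNM axes plus two environmental PCs
already span it; the partial db-RDA tests handle the residual ranks and
raise an informative error when a predictor set is fully collinear with
its condition set.

## Distance decay and variation partitioning

DDR is ordinary least squares of the vectorized upper-triangle
dissimilarity on log10-transformed predictor distance.  Zero predictor
distances are handled by `zero_policy`: the default adds an offset before
the log (1 km for geographic distances; one tenth of the smallest
positive distance otherwise); an exclusion mode is provided.  OLS on
distance pairs ignores pair non-independence; this replicates the
field convention and its p-values carry the same caveat.  The bootstrap
resamples *samples* (not pairs): 1000 draws of 21 samples without
replacement, refitting the DDR each time; slope distributions are
compared by two-sided Mann–Whitney with tie correction.

Variation partitioning is db-RDA on the Gower-centered community matrix:
R²(X) = tr(HGH)/tr(G) with H the hat matrix of [1, X], adjusted by
Ezekiel's formula 1 − (1−R²)(n−1)/(n−p−1); fractions are
[a] = adjR²(geo+env) − adjR²(env), [c] symmetric, [b] by inclusion–
exclusion, [d] the residual; a+b+c+d = 1 exactly, and slightly negative
adjusted fractions are reported rather than clipped.  Fraction tests
permute the (residualized) response matrix: without a condition set, rows
and columns of G; with one, the Freedman–Lane-style residual matrix
(I−H_z)G(I−H_z) with the predictor residualized on the condition set.

## Assembly processes

βMNTD for a pair is the abundance-weighted (default; presence-weighted
optional) mean patristic distance from each taxon to its nearest taxon in
the partner community, halved and symmetrized.  The null shuffles tip
labels across the whole phylogeny; one shuffle per replicate is shared
across all pairs (statistically equivalent per pair marginally, and the
cost of the matrix recomputation is amortized over all pairs); per-pair
independent shuffles are available behind a flag.  βNTI is the z-score
against 999 nulls.  Pairs whose null sd is zero (e.g. literally identical
communities, whose shared membership survives any relabeling) are flagged
undefined and excluded from summaries with a warning.  βNTI is invariant
to rescaling all branch lengths (tested) and is calibrated —
signal-free assemblies give mean ≈ 0, sd ≈ 1 (tested).

RC_Bray nulls preserve each sample's observed richness and total count:
species are drawn without replacement with probability proportional to
metacommunity occurrence frequency (Gumbel top-k weighted sampling), each
drawn species receives one individual, and the remainder is allocated
multinomially by metacommunity relative abundance among the drawn
species.  RC = 2[(#{BC_null < BC_obs} + ½#{BC_null = BC_obs})/n_null] − 1
(half-weight ties; equality at 1e−12 float tolerance).  The metacommunity
defaults to the analysed table (occurrence and summed abundance);
explicit pools can be supplied, which the null-self-consistency test uses
to avoid the re-estimation circularity.  Nulls are computed once per
sample per replicate and shared across the pairs of that replicate.

Classification uses strict inequalities (boundary values fall to the
stochastic/drift side): βNTI > 2 variable selection; βNTI < −2
homogeneous selection; else RC > 0.95 dispersal limitation; RC < −0.95
homogenizing dispersal; else drift.  One null is computed per habitat
over all its samples; cross-habitat pairs are never classified.
Summaries split pairs into intra-site and inter-site per habitat.

## Synthetic metacommunity generator

The generator is the testbed: it encodes the habitat-specificity gradient
mechanistically and every downstream claim is checked against it.

* **Phylogeny**: pure-birth (Yule) tree, unit rate; expected root-to-tip
  depth Σ_{k=2..n} 1/k (tested by Monte Carlo).  **Niche optima**:
  Brownian motion from a root value of 0; sibling covariance equals
  shared path length × variance (tested).
* **Sites**: the five study localities with their real coordinates
  (geodesic span ≈ 800–8100 km among the Atlantic-sector sites, ~16,000 km
  to Kerguelen in the full design) and depths.  The latent environment's
  first axis follows standardized latitude — the spatial structure that
  species sorting converts into distance decay — and remaining axes are
  independent site effects.  The observable environmental table adds a
  near-duplicate of axis 1 (Pearson r > 0.95, to exercise pruning) and
  two pure-noise variables.
* **Communities**: per-sample OTU weights are lognormal metacommunity
  abundances (σ = 2.0, so per-sample richness is well below the pool
  size — the regime in which occupancy-constrained nulls are informative)
  times a Gaussian selection filter exp(−s·‖optimum − env‖²) with
  habitat-specific strength s, optionally masked to a per-sample random
  subset of the pool (`richness_scale`, the island-like colonization of
  gut habitats), perturbed by Dirichlet noise with total concentration
  1/`drift_intensity`, mixed with the metacommunity pool at the habitat's
  `dispersal_rate`, and drawn multinomially at the configured depth.
* **Habitat defaults** (the gradient): sediment (richness_scale 1.0,
  s = 1.5, dispersal 0.30, drift 0.001), gut content (0.6, 0.7, 0.15,
  0.02), gut tissue (0.25, 0.3, 0.05, 0.3).  These were chosen so that
  the generator expresses the gradient's signatures — declining richness
  and niche breadth, declining site differentiation, within-site
  homogenization in sediment versus island-like gut tissue — at the
  simulated depths.

The per-process pair generator (`simulate_under_process`) produces
ground truth for the classifier: *homogeneous selection* admits one
internal clade (10–35% of a 400-taxon pool) with a per-sample Dirichlet
lottery within it — the limiting case of a perfectly conserved niche
filter, chosen because a trait-Gaussian filter centred mid-range selects
phylogenetically mixed taxa (every lineage crosses the trait centre) and
produces no βNTI signal; *variable selection* uses strong Gaussian
filters at optima ±2 trait SD (opposite phylogenetic tails); *homogenizing
dispersal* resamples one community at 75% weight; *dispersal limitation*
draws from disjoint random halves of the pool; *drift* draws
independently from the shared pool.

**What passing tests show — and don't.**  The synthetic experiments show
the *machinery* is correct and calibrated and that the qualitative
habitat-gradient predictions follow from the stated mechanisms.  They do
not reproduce the real dataset's numbers: the generator has no taxonomy,
no sequencing error, no temporal variation, no host genetics or vertical
transmission, and its site environments are low-dimensional.  One known
divergence: between sites the synthetic classifier output is dominated by
dispersal limitation rather than variable selection, because the latent
site environments mostly differ by ~1 trait SD and differential selection
of that size is not phylogenetically clustered enough to push βNTI beyond
+2; the real study's inter-site variable selection reflects stronger,
higher-dimensional environmental contrasts.

## Problem sizes

Default analyses use 999 permutations (PERMANOVA, fraction tests), 999
null-model replicates, and 1000 × 21-sample bootstraps.  The acceptance
script runs the full 200-sample design with an 800-OTU pool (the real
dataset has 1247 OTUs after filtering) and 999 nulls, about one minute on
one CPU.  The test suite's gradient checks use 20 seeded runs of a
trimmed design (4 samples per site × habitat, 600 OTUs, 199 nulls) and
the recovery checks use 50 pairs × 999 nulls per scenario, keeping the
whole suite within a few minutes.

## Known limitations

* Vincenty's method fails near antipodal point pairs (error raised).
* OLS-based DDR inherits pair non-independence; a Mantel-style analysis
  is out of scope.
* Single rarefaction; permutational rarefaction is not implemented.
* PERMANOVA supports one-way designs (site, habitat, host) without
  strata, matching the analyses performed here.
* The RC null's tie tolerance (1e−12) matters only for literally
  duplicated count vectors.
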