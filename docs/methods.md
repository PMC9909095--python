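# Methods

This note documents the models implemented in `microbiogeo`, the
conventions and numerical choices behind them, what the synthetic
metacommunity generator does and does not emulate, and the package's known
limitations.

## The assembly null-model framework

For every pair of communities the between-community mean nearest taxon
distance is

βMNTD(a, b) = ½ [ Σᵢ∈a fᵢᵃ · minⱼ∈b d(i, j) + Σⱼ∈b fⱼᵇ · minᵢ∈a d(j, i) ],

where d is the cophenetic (patristic) distance on the supplied tree and f
are within-sample relative abundances (abundance weighting is the default;
a taxon shared by both samples contributes a nearest distance of zero).
The null model shuffles taxon labels across the tips of the *regional*
tree — all taxa of the metacommunity, one permutation applied jointly to
both samples — and βNTI is the standardized effect size
(observed − null mean)/null sd over `n_null` randomizations (default 999).
βNTI > +2 is read as heterogeneous selection, βNTI < −2 as homogeneous
selection; both inequalities are strict, so boundary values fall through to
the stochastic classification. Pairs whose null standard deviation is zero
(possible when both samples contain identical taxon sets, or on a star
phylogeny) are flagged NaN, excluded from fractions and counted in the
output — never silently dropped.

Efficiency note: for each permutation the vector of nearest-member
distances from every taxon to each sample's members is computed once, so an
all-pairs βNTI run costs O(nulls × samples × taxa × richness) rather than
O(nulls × pairs × richness²).

For pairs inside the ±2 band, RC_bray assembles both communities from the
regional pool independently per randomization: the observed richness of
each sample is drawn without replacement with probability proportional to
occupancy frequency (number of samples containing the taxon), then the
observed read total is allocated among the drawn taxa multinomially with
probability proportional to regional summed abundance.
RC = 2·[(#null < obs) + ½·(#null = obs)]/n_null − 1 ∈ [−1, 1]; ties count
half so RC is symmetric. RC > +0.95 → dispersal limitation, RC < −0.95 →
homogenizing dispersal, otherwise drift (again strict inequalities).
Process fractions are tallied per stratum over pairs whose two samples both
belong to the stratum, plus an "all" row.

## Diversity conventions

- Shannon uses the natural log, so Pielou's J = H/ln S exactly; J is
  flagged NaN (not zero) for single-taxon samples.
- Simpson is the Gini–Simpson form 1 − Σp², bounded in [0, 1].
- Faith's PD is rooted: the minimal subtree connecting the present tips
  always includes the path to the root. Stated explicitly because the
  unrooted convention differs.
- Rarefaction is a single uniform without-replacement draw per sample
  (multivariate hypergeometric), not an average over draws; samples below
  the target depth are dropped with a logged warning, and taxon rows are
  never pruned so axes stay comparable.
- β-diversity is computed on rarefied counts after Hellinger
  transformation, in that order.
- The Wilcoxon rank-sum test enumerates all rank splits exactly (average
  ranks on ties) when n₁+n₂ ≤ 12 and uses the tie-corrected normal
  approximation otherwise.
- PCoA reports every eigenvalue of the double-centred −D²/2 matrix,
  negative ones included, but coordinates span only the
  positive-eigenvalue axes.

## Co-occurrence networks

Order-level relative abundances (column sums preserved), removal of orders
with mean relative abundance strictly below 1 % (exactly 1 % is retained),
Spearman ρ with average ranks and two-sided p from the t-distribution
transform, and the joint gate |ρ| > 0.4 ∧ p < 0.05. No multiple-testing
correction is applied by default — the raw-p gate is the convention this
pipeline follows — but a Benjamini–Hochberg option exists for sensitivity
analyses. Correlations are computed on relative abundances (the filter is
defined on them); the compositional caveat applies, as it does to any
correlation-based network on closed data. Undefined ρ (zero-variance
orders) never produces an edge. The t-transform p tracks the exact
permutation distribution to ≈0.03 at n = 8 (tightest in the tails); the
permutation-exact tail behaviour is what the edge gate relies on.

## Spatial drivers

- Geographic distance is great-circle (haversine, R = 6,371 km); ocean
  currents are not modelled, so along-current connectivity is addressed
  only through stratified comparisons.
- Mantel: Pearson or Spearman on the lower triangles; simultaneous
  row/column permutation of one matrix; one-sided "greater" by default.
  When n! ≤ nperm all permutations are enumerated and the p-value is
  exact.
- PERMANOVA is one-factor, computed from squared distances
  (SS_total = Σ_{i<j} d²/N; SS_within summed per group; pseudo-F with
  (k−1, N−k) degrees of freedom). An optional `strata` argument restricts
  permutations to within-block shuffles. This matters in the balanced
  stations × depths design: freely permuted labels are a badly
  conservative null for the factor orthogonal to the dominant gradient
  (measured station-level rejection ≈ 0–1 % at α = 5 % whenever depth
  structures the distances), whereas within-depth permutation restores
  nominal calibration. The depth test itself uses free permutations.
- PCNM/dbMEM: distances above the longest minimum-spanning-tree edge are
  replaced by 4t, the truncated matrix is double-centred and
  eigendecomposed, and positive-eigenvalue eigenvectors are returned in
  decreasing order. Output matches `vegan::pcnm` up to sign. The default
  number of eigenfunctions used as spatial predictors is 5. Forward
  selection is deliberately out of scope.
- RDA is transformation-based: least-squares projection of the centred
  Hellinger table onto standardised predictors; adjusted R² by Ezekiel,
  flagged NaN when n ≤ p + 1; collinear predictors are dropped greedily by
  rank with a warning.
- Variation partitioning: [a+b], [b+c], [a+b+c] from the three RDA fits,
  the rest by inclusion–exclusion; fractions sum to 1 by construction, and
  small negative adjusted fractions are reported as computed with a flag,
  never clipped.

## The synthetic metacommunity generator

The generator exists to give every downstream stage ground truth; it is a
deliberate mechanistic stand-in, not a fitted model of any real water
column (the field study it emulates is observational).

**Design.** 8 stations on two latitude rows ("sections", 13° N / 15° N)
spanning ~1,100 km east–west; six depth layers (5 m, 75 m, DCM, 200 m,
500 m, 3,000 m); per-layer environmental base profiles with temperature
strictly decreasing and TIN/DIP/silicate strictly increasing with depth,
chlorophyll a peaking at the DCM and exactly zero below 200 m, and
dissolved oxygen rising to 75 m then declining. Station-level noise is
bounded below half the smallest between-layer gap so the monotone
gradients hold at every station by construction.

**Phylogeny and niches.** Trees are pure-birth (Yule), ultrametric, with
strictly positive branch lengths. Niche optima evolve by Brownian motion
(root 0; tip variance σ_BM² × depth). A plain BM trait on a Yule tree,
however, carries almost no nearest-taxon signal: most pairwise divergences
date to deep nodes, sister taxa differ in trait by a large fraction of the
total spread, and trait-similar taxa are barely closer on the tree than
random ones. Real marker-gene phylogenies behave differently — habitat
preferences are conserved at coarse clade level. The generator therefore
evolves traits on a node-age power-transformed copy of the tree
(`niche_conservatism`, default exponent 3: node age a ↦ H·(a/H)³, height
preserved), which concentrates niche divergence in deep splits while
βMNTD continues to use the untransformed tree. The BM contract (tip
variance = σ² × depth) holds on whichever tree the trait is evolved on.

**Selection regimes.** Each sample first receives a stochastic colonist
pool (every taxon arrives with probability `colonization`, default 0.7),
then colonists are weighted by exp(−(trait − env)²/2σ²) with
σ = `sigma_niche` × sd(traits) (default 0.1, i.e. strong filtering), and
reads are drawn multinomially. The colonization lottery is essential:
without presence turnover two equally-selected communities share their
taxon sets, shared taxa contribute zero nearest-taxon distance to both the
observed and the label-shuffled null, and homogeneous selection becomes
undetectable by construction. Under heterogeneous selection the per-sample
environments sweep the full realized trait range (as the vertical
temperature gradient spans the community's whole thermal niche space);
`env_by_depth=True` instead assigns six shared levels keyed to the depth
layers. Homogeneous selection gives every sample the median trait value.

**Neutral regimes.** Drift starts all samples from a uniform common pool
and applies `generations` rounds of per-sample multinomial resampling
(default 300 at 2,000 reads — enough for the accumulated divergence to
match what the occupancy-based Raup–Crick null itself predicts; with far
fewer rounds observed dissimilarity sits above a tight multinomial-floor
null and pairs misclassify as dispersal limitation). Dispersal limitation
uses weak spatially-decaying immigration (m·exp(−d/d₀), d₀ = inter-station
spacing, m = 0.02); homogenizing dispersal mixes uniformly (m = 0.85)
because a distance-decaying kernel would itself imprint the spatial
structure whose absence the regime is meant to demonstrate.

**What passing tests do and do not show.** Parameter recovery on these
scenarios demonstrates that the implementation of βMNTD/βNTI/RC_bray and
the classification thresholds behaves correctly on data with known
structure at realistic signal strengths. It does not validate the
ecological interpretation of the framework on field data, where trait
dimensionality, unmeasured gradients, sequencing artefacts and tree
uncertainty all intervene.

**Known limitation.** The homogenizing-dispersal regime classifies
predominantly as drift under this generator: full mixing drives observed
Bray–Curtis to the multinomial sampling floor, which the read-allocation
null also attains, so RC cannot fall below −0.95. Detecting homogenizing
dispersal requires observed similarity beyond the sampling floor (e.g.
shared structured deviations from the regional mean), which no
read-resampling mechanism produces. The regime is kept because its other
signatures (no distance decay, βNTI within ±2) are exercised by the
spatial tests.

## Reproducibility

Every randomized operation takes an explicit seed. The pipeline derives
per-stage seeds from the master seed by a fixed rule
(`core_io.stage_seed`: the pair (master, stage-id) keys a
`numpy.random.SeedSequence`), so full runs are bit-for-bit reproducible at
fixed null counts. Scenario scales used by the test-suite and the
acceptance script (e.g. 200 taxa × 16 samples × 2,000 reads × 199 nulls
for regime recovery; 120 taxa × 48 samples for the depth-pattern checks)
were chosen as the smallest sizes at which the targeted signals are
comfortably resolved; the library itself has no scale assumptions beyond
memory.
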