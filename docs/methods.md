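# Methods

## Model and assumptions

The method treats a tumor cohort's bulk expression profiles as samples from
a low-dimensional, possibly nonlinear "expression space" whose structure
(molecular subtypes and sub-subtype flares) is reconstructed as a Mapper
network, and defines a candidate cancer gene as one whose nonsynonymous
mutations concentrate in a connected region of that network. The central
assumptions are:

- driver mutations are accompanied by consistent global expression
  programs, so their carriers are near one another in correlation distance;
- passenger mutations are exchangeable across patients, so patient-label
  permutation is the correct null;
- confounded concentration has three identifiable sources — globally
  hypermutated tumors with a distinctive expression phenotype, per-gene
  coupling between expression level and mutation rate, and batch effects —
  each of which can be tested and corrected on the same representation.

Under these assumptions the method gains sensitivity for low-prevalence
genes precisely where recurrence-based methods lose it: a gene mutated in
3% of tumors is undetectable by counting, but 9 carriers concentrated in
one subtype of a 300-patient cohort is a strong permutation signal.

## Topological representation

- **Metric.** Pearson correlation distance `d = 1 − r` between samples over
  the 4500 most-variable genes (transformed scale, unbiased variance, ties
  broken by gene id).
- **Filter.** A k = 30 nearest-neighbor graph (union-symmetrized, edges
  weighted by distance) gives all-pairs geodesic distances, embedded in 2-D
  by classical (Torgerson) MDS. Eigenvalues at round-off scale are zeroed
  so exactly low-dimensional geometry embeds exactly; eigenvector signs are
  fixed by making each axis's largest-magnitude loading positive, so the
  construction is fully deterministic. A PCA filter is available as the
  supported alternative.
- **Disconnected graphs.** Strongly separated subtypes disconnect a kNN
  graph. Every component pair is bridged by its single shortest
  inter-component edge at the original distance. Bridging with a spanning
  tree instead would route all between-component geodesics through
  whichever component sits in the middle, stretching it in the embedding
  and dissolving its cluster structure — in testing this silently destroyed
  sensitivity for drivers in the central subtype, which is why the
  all-pairs rule is the default and the event is logged loudly.
- **Cover.** Per axis, `resolution` interval centers span [min, max] with
  spacing s; each interval has width s × gain (inclusive boundaries), so
  adjacent intervals overlap by 1 − 1/gain. Bins are the Cartesian
  products; empty bins are dropped. A degenerate axis (zero range) becomes
  a single interval.
- **Per-bin clustering.** Single linkage on the original distances. The cut
  sits at the left edge of the first *gap* in the merge-height histogram
  (10 equal-width bins over [0, max height]) — the first empty histogram
  bin that follows an occupied one. Leading empty bins below the smallest
  merge height are not gaps: cutting there (a literal "first empty bin"
  rule) would shatter every bin whose minimum merge height exceeds a tenth
  of its maximum into singletons and destroy the nerve. With no gap, or all
  heights zero, the bin is one cluster.
- **Nerve.** One node per cluster; binary, zero-diagonal adjacency with an
  edge wherever two nodes share a sample.

## Localization statistic

C(g) = N/(N−1) · Σ_{i,j} eᵢ A_ij e_j / (Σ_k e_k)², with e_i the fraction of
node i's members carrying ≥ 1 nonsynonymous mutation in g (multiplicity
ignored). The double sum runs over ordered pairs; the public
`localization_score` evaluates it as a literal double loop (the
definitional form), while the permutation engine rewrites it as a quadratic
form M = Wᵀ A W over samples (W the row-normalized membership matrix), so a
permutation of a binary feature is a sum over an index submatrix of M. The
two paths agree to 1e-12 and the engine is what makes 10⁴ permutations per
gene affordable.

P-values use the add-one estimator p = (1 + #{C_perm ≥ C_obs})/(1 + n_perm)
— the permutation distribution always contains the observation, p can never
be zero, and a permutation-invariant feature gets p = 1 (ties are counted
with a 1e-9 relative tolerance to absorb float summation-order noise).
Per-gene permutation streams are seeded as
`(seed · 1000003 + crc32(gene)) mod (2³¹ − 1)`, so results are independent
of gene order and reproducible under parallel evaluation. BH adjustment is
applied over exactly the tested gene set (via statsmodels); significance
means q < 0.15.

Genes enter the test set when their cohort prevalence reaches a per-cohort
threshold (`prevalence_min`, deliberately without a default — it trades BH
correction size against coverage and belongs to the analyst), ranked by
nonsynonymous/total mutation ratio and truncated to 350.

## Confound controls

**Burden.** The node feature is the mean total mutation count (all variant
classes). If its localization p < 0.05, each hypermutated sample (burden >
threshold; "auto" = 10^2.5) is downsampled without replacement to the
nonhypermutated median burden; per-sample targets alternate between the
floor and ceiling of a half-integer median so the two medians can match
exactly (an odd number of hypermutated samples against a half-integer
median is off by half a mutation, and logged). A cohort still significant
after subsampling is excluded unless explicitly overridden.

**Expression–mutation anticorrelation.** For each gene, the normalized
mutation profile ẽ (carrier fractions) and expression profile r̃ (per-node
mean *abundance*, `2^r − 1`) are compared by Jensen–Shannon divergence
(natural log, J ∈ [0, log 2]), against `2000` patient-label permutations;
the lower-tail p is small for correlated genes, large for anticorrelated
ones. Three design points deserve emphasis:

- *Abundance scale for r̃.* On the log scale, per-node mean expression is
  nearly flat for every gene (a ±1 log2 noise band averaged over 10–30
  samples), so no gene's expression profile can visibly align or misalign
  with its mutation profile; on the abundance scale subtype-level
  expression differences give r̃ real dynamic range. This mirrors the fact
  that the log transform exists for the correlation metric, not for
  averaging.
- *Sign guard.* J is an unsigned divergence, and a strongly localized
  gene's mutation profile is spikier than any permuted scattering — its J
  lands in the upper tail whatever its expression does. Removal therefore
  additionally requires a negative Pearson correlation between the mutation
  profile and the log-scale expression profile (log, because mutation cis
  effects on expression are additive there and the guard should not depend
  on baseline abundance). Without the guard the filter strips genuine
  drivers; with it, planted anticorrelated genes are removed at ≥ 85%
  sensitivity while ≤ 2% of neutral passengers are touched.
- *Default removal rule.* BH-adjust the upper-tail p across the tested
  genes within each representation and remove when the median adjusted
  value across the parameter space falls below 0.2 (and the sign guard
  agrees). The printed alternative — BH on the lower-tail p with removal at
  median q > 0.8 — is available as `js_mode="literal"`, but under a
  complete null BH pushes ~90% of adjusted values above 0.8, so the literal
  rule removes most neutral genes; it is retained only for comparability.

**Batches.** Per batch, the membership-fraction feature is tested exactly
like a gene; batches with p < 0.05 are flagged and their samples excluded
from the mutation-side statistics (profiles and permutations). The
representation itself is never rebuilt — dropping samples before Mapper
would change the space being tested. Unlabeled samples become singleton
batches (logged); a batch covering the whole cohort is permutation-invariant
and can never be flagged.

## Parameter scan, selection, aggregation

The coarse grid spans resolutions 10–80 (step 10) and gains 1.5–8.5 (step
1); custom ranges are honored verbatim. The JS filter pools its decision
across the coarse representations (median of the per-representation
adjusted values), and region selection then scores contiguous windows of
confound-clean cells by their mean count of significant genes — counted
*after* gene removal, so spuriously localized genes cannot steer the
selection (ties prefer smaller resolution, then smaller gain). The selected
region is rescanned at steps 5 (resolution) and 0.5 (gain) on the retained
genes, and per-gene q is aggregated as the median (with quartiles) over the
fine cells; a gene dropped in some cell counts there as q = 1. Stability is
summarized as the median pairwise Pearson correlation of the per-gene C
vectors across cells.

For desk-scale cohorts (a few hundred samples) the package's evaluation
protocol subsamples this grid: resolutions {10, 20, 30, 40} (above that,
bins hold single samples and the nerve degenerates into per-sample cliques
with no statistical power) and gains {2.5, …, 6.5}, with a selection window
of one resolution row × two gain steps — consecutive coarse resolutions
double the bin scale at n ≈ 300, so a two-row window mixes incompatible
node sizes and the aggregated medians lose the signal the selection found.
Power increases with gain (wider overlap → larger nodes → more carrier
co-occurrence), so the scan's gain axis matters more than its resolution
axis at this cohort size.

## Synthetic cohorts

`simulate_cohort` draws, from a single mandatory seed: subtype-clustered
expression (gene baselines ~ U(2, 10) on the transformed scale, per-subtype
marker shifts of 3 noise s.d. on 10% of genes, Gaussian noise, clipped at
0); drivers confined to a subtype at 3–15% cohort prevalence with a +2 s.d.
cis expression effect in carriers; uniformly scattered passengers (Poisson
8 events/sample, 30% silent, so the nonsynonymous/total ratio filter has
work to do); hypermutated samples (default 2, 50× passenger rate) carrying
a 200-gene expression signature — the MSI/POLE-like phenotype that makes
excess burden localize and hence detectable; optional genes whose mutation
probability is exponential in ±(their own z-scored expression); and random
or subtype-aligned batches. Subtype markers are drawn only from unmutated
filler genes so the planted truth classes (cis-correlated driver, neutral
passenger, anticorrelated coupled gene) are unambiguous.

What the generator does **not** emulate: heavy-tailed TCGA expression
marginals, gene–gene correlation beyond subtype block structure, realistic
mutational signatures or per-gene background rates, copy-number effects,
tumor purity variation, or continuous (non-clustered) expression manifolds.
Passing tests therefore establish that the implementation is correct and
that the method behaves as designed *when its assumptions hold* — not that
it attains the same operating characteristics on real cohorts, where the
expression space is richer and the confounds messier.

## Numerical choices and degenerate inputs

- kNN edge weights are clamped to ≥ 1e-12 so zero-distance pairs remain
  edges in the sparse graph.
- Permutation tie counting uses a 1e-9 relative tolerance; the JS test uses
  1e-12 absolute.
- Normalized profiles must sum to 1 within 1e-9; 0·log 0 = 0 throughout.
- All-zero features, single-node graphs, empty gene lists, all-hypermutated
  cohorts, unnormalizable profiles and empty fine-scan regions raise
  descriptive errors; genes with no mutations among kept samples are
  dropped with a logged count.
- Everything downstream of a seed is deterministic, including across
  process restarts; the Mapper construction itself uses no randomness.

## Known limitations

- The burden localization test loses power when hypermutated tumors lack an
  expression phenotype (their nodes dilute the burden spikes); their excess
  passengers then inflate gene-level scores undetected. This is a property
  of the method, visible in simulation when the hypermutator signature is
  removed.
- The JS filter cannot distinguish a genuinely anticorrelated driver (e.g.
  a tumor suppressor silenced by nonsense-mediated decay in its carriers)
  from a repair artifact; such genes are removed.
- Statistical power is concentrated at cover scales where bins hold several
  samples; for small cohorts the useful resolution range is narrow and the
  region-selection step is essential rather than cosmetic.
- Aggregating q by median across cells assumes the selected region is
  homogeneous; selecting windows that straddle a power cliff degrades
  recovery, which is why the evaluation protocol keeps the window within
  one resolution row.
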