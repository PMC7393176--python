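# topodriver

Identification of cancer-associated mutated genes from the *localization* of
their mutations in a tumor cohort's expression space.

Recurrence-based driver discovery needs many patients carrying the same
mutated gene, so genes mutated in only 1–5% of tumors are largely out of
reach. `topodriver` implements a complementary, expression-based definition:
a candidate cancer gene is one whose carriers occupy a *connected region* of
the cohort's transcriptional space, on the premise that driver mutations are
accompanied by consistent global expression programs while passengers
scatter at random. The package is aimed at computational cancer-genomics
researchers working with matched bulk RNA-seq (RSEM-style TSV) and somatic
mutation calls (MAF).

## Method

1. **Topological representation.** Expression values are transformed as
   `r = log2(1 + 1e6·x)`. Sample–sample Pearson correlation distances over
   the top 4500 most-variable genes feed a `k = 30` nearest-neighbor graph;
   the 2-D classical-MDS embedding of its geodesic distances is the Mapper
   *filter*. An overlapping square cover (parameters: `resolution` = bins
   per axis, `gain` = overlap; interval width = spacing × gain) is clustered
   per bin by single linkage with a merge-height-gap cut. Each cluster is a
   node; nodes sharing a tumor are joined by an edge.

2. **Localization score.** For a gene *g* with per-node nonsynonymous
   carrier fraction *eᵢ*, on the node set Γ (|Γ| = N) with adjacency *A*:

   C(g) = N/(N−1) · Σ_{i,j∈Γ} eᵢ A_ij e_j / (Σ_k e_k)²

   C is scale-invariant in *e* and sums the co-occurrence of carriers along
   edges. Significance comes from permuting patient labels of the mutation
   data (default 10⁴ permutations, add-one p-value), with Benjamini–Hochberg
   FDR control across the tested genes; genes are significant at q < 0.15.

3. **Confound controls.** (a) Localized mutational *burden* (hypermutated
   tumors with a distinctive expression phenotype) triggers per-sample
   subsampling to the nonhypermutated median burden; cohorts that stay
   burden-localized are excluded. (b) A Jensen–Shannon permutation filter
   removes genes whose own expression anticorrelates with their mutation
   profile across the network (transcription-coupled-repair-like artifacts).
   (c) Batches whose membership localizes (p < 0.05) are excluded from the
   mutation-side statistics.

4. **Parameter scan.** The analysis is repeated over a resolution × gain
   grid (coarse default 10–80 × 1.5–8.5), a window maximizing the number of
   significant genes among confound-clean cells is selected, a finer scan
   (steps 5 and 0.5) covers it, and per-gene significance is aggregated as
   the median q across cells.

Gold-standard benchmarking (precision, recall and F1 over the top
min(15, G) significant genes), cohort-downsampling experiments with
label-permuted nulls, and Fisher exact overlap tests are provided in
`topodriver.benchmark`. A fully seeded synthetic-cohort generator
(`topodriver.simulate`) plants drivers, passengers, hypermutators,
expression-coupled genes and batches with known truth.

## Worked example

```python
from topodriver import AnalysisConfig, CohortConfig, DriverLocalization, simulate_cohort

expression, mutations, truth = simulate_cohort(CohortConfig(seed=0))
model = DriverLocalization(expression, mutations,
                           AnalysisConfig(prevalence_min=0.02, seed=0))
results = model.fit(resolution=10, gain=4.5, n_perm=1000, js_n_perm=500)
print(results.summary())
```

```
                   Topological Mutation Localization
========================================================================
No. samples                                                          300
No. tested genes                                                     193
Removed by JS filter                                                   0
Mapper resolution / gain                                        10 / 4.5
Nodes in representation                                              111
Burden control p (initial/final)                        0.000999 / 0.323
Hypermutators subsampled                                            True
Significant genes (q < 0.15)                                           5
------------------------------------------------------------------------
  gene  prevalence      C        p       q  significant  n_permutations
 DRV01        0.04 0.8216 0.000999 0.03856         True            1000
 DRV02        0.04 0.9359 0.000999 0.03856         True            1000
 DRV03      0.1167 0.7418 0.000999 0.03856         True            1000
 DRV04        0.04 0.8023 0.000999 0.03856         True            1000
 DRV05        0.06 0.7406 0.000999 0.03856         True            1000
PSG076        0.03 0.6928 0.004995  0.1607        False            1000
...
```

The five significant genes are exactly the five planted drivers (including
three at 4% prevalence), the mutational burden was initially localized
(p ≈ 0.001, the two planted hypermutators) and resolved after subsampling
(p ≈ 0.32), and the top passengers fall short of the q < 0.15 cut. The
`results` object also carries the network (`results.representation`, with
GraphML/JSON export) and the confound report; `model.fit_scan(fine=True)`
runs the full scan–select–refine protocol and aggregates median q per gene.

A command-line interface mirrors the library:

```bash
topodriver simulate --out cohort/ --seed 0
topodriver run-full --expression cohort/expression.tsv --maf cohort/mutations.maf \
    --already-transformed --prevalence-min 0.02 --seed 0 --out run/
topodriver benchmark --fisher 13 276 0 181
```

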