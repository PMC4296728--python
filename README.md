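# microbiome-cc

Case–control analysis of fecal microbiome composition from a rarefied OTU
table: did people with some binary exposure history (e.g. cesarean birth,
appendectomy) end up with a distinguishable gut microbial community?

The package is aimed at microbiome epidemiologists working with American-Gut
style inputs — a classic OTU-table TSV with greengenes lineage strings
(`p__Firmicutes;c__Clostridia;...`), a per-sample metadata TSV, and
optionally a rooted newick tree — and implements the whole workflow:

1. **Cleaning** — ordered exclusion filters (age < 4, missing sex/race,
   non-fecal specimens, recent antibiotics, diabetes, IBD, duplicate
   participants) with an attrition report.
2. **Taxonomy collapse** — sum taxa sharing a lineage prefix at each rank
   from phylum down to species; unnamed ranks (`g__;s__`) stay distinct.
3. **Alpha diversity** — richness, Shannon entropy, bias-corrected Chao1,
   inverse Simpson, and Faith's whole-tree phylogenetic diversity.
4. **Beta diversity** — pairwise Jensen–Shannon divergence at every level.
   For compositions *Pⁱ*, *Pʲ* with midpoint *Q = (Pⁱ+Pʲ)/2*,

   JSD(Pⁱ, Pʲ) = ½ D_KL(Pⁱ‖Q) + ½ D_KL(Pʲ‖Q),  D_KL(P‖Q) = Σₖ pₖ log(pₖ/qₖ),

   symmetric and bounded by ln 2.
5. **Group-clustering permutation test** — observed statistic: mean pairwise
   JSD among case samples; null: B random relabelings; one-sided p-value
   (1 + #{null ≤ obs}) / (1 + B) for the case group being unusually tight.
   Exhaustive enumeration is available for small n.
6. **Community clusters** — average-linkage hierarchical clustering on the
   JSD matrix cut to K clusters, with a Pearson chi-square K×2
   cluster-by-case test and newick dendrogram export.
7. **Taxon screening** — per-taxon logistic regression of case status on
   relative abundance adjusted for age, sex and race; Wald p-values with
   Benjamini–Hochberg q-values, pooled across all taxonomic ranks.

A Dirichlet-multinomial simulator (`simulate_dataset`) generates case–control
datasets with known ground truth — fixed sequencing depth, overdispersed
compositions, a configurable multiplicative concentration shift on a subset
of taxa in cases, and age-confounded case assignment — so the whole pipeline
is testable end to end with no external data.

## Worked example

```python
import microbiome_cc as mcc

ds = mcc.simulate_dataset(mcc.SimulationConfig(
    n_cases=15, n_controls=25, n_taxa=40, effect_size=3.0, seed=5))
rel = mcc.to_relative(ds.table)
genus = mcc.collapse_to_level(rel, "genus")
D = mcc.divergence_matrix(genus, "genus")
res = mcc.group_clustering_permutation_test(
    D, (ds.metadata["CSECTION"] == "yes").to_numpy(), B=999, seed=1)
print(f"within-case mean JSD = {res.observed:.4f}, p = {res.p_value:.3f}")
```

prints

```
within-case mean JSD = 0.1231, p = 0.196
```

— the 15 simulated cases have a mean pairwise genus-level divergence of
0.1231 nats, not unusually tight against 999 relabelings at this small n
(the same shift at n = 100+100 is detected essentially always; see the
calibration/power quantities below).

The same analysis runs from the shell:

```bash
microbiome-cc simulate --n-cases 15 --n-controls 25 --n-taxa 40 --seed 5 --out-dir sim/
microbiome-cc analyze --table sim/otu_table.tsv --metadata sim/metadata.tsv \
    --tree sim/tree.nwk -B 999 --seed 1 --out-dir sim/run
microbiome-cc report sim/run
```

`analyze` writes the attrition report, per-level divergence matrices and
permutation p-values, the dendrogram, cluster assignments and the
cluster-by-case chi-square, per-sample alpha diversity, per-variable
covariate regressions, the pooled taxon screen, and a JSON manifest that
makes the run bit-for-bit reproducible.

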