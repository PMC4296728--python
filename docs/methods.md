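# Methods

## Problem and model

The package tests whether a binary exposure history is associated with the
*composition* of the adult gut microbiome, given a taxon count table already
rarefied to a common depth. Composition per subject *i* at a taxonomic level
with K taxa is the relative-abundance vector *Pⁱ*. Dissimilarity between
subjects is the Jensen–Shannon divergence

JSD(Pⁱ, Pʲ) = ½ D_KL(Pⁱ‖Q) + ½ D_KL(Pʲ‖Q),  Q = (Pⁱ+Pʲ)/2,

with D_KL(P‖Q) = Σₖ pₖ log(pₖ/qₖ) and the conventions 0·log(0/q) = 0 and
D_KL = ∞ when P puts mass outside Q's support. Because Q dominates both
arguments, JSD is always finite, symmetric, zero iff the compositions are
equal, and bounded by log 2. Natural log is the default everywhere (bound
ln 2 ≈ 0.693); `base=2` is available since the QIIME-era tooling sometimes
used bits. All divergence code paths compute the two K–L terms explicitly;
the algebraic identity JSD = H(Q) − (H(Pⁱ)+H(Pʲ))/2 is used only as an
independent cross-check in the tests.

## Group-clustering permutation test

The question "are cases compositionally clustered?" is operationalised as:
**is the mean pairwise JSD among case samples smaller than expected if case
labels were arbitrary?** The observed statistic is the within-case mean of
the divergence matrix; the null distribution comes from B random
re-assignments of the case-set size over all samples; the one-sided p-value
uses the add-one convention p = (1 + #{null ≤ observed}) / (1 + B), which
can never be zero and is exact under exchangeability. This within-group mean
was a genuinely open design choice — a within-minus-between contrast is just
as defensible and is available via `statistic="within_minus_between"` — and
it is the single most consequential interpretive decision in the package.

The two-sided option reports min(1, 2·min(p_case, p_control)), the
Bonferroni combination of the two groups' one-sided tests. This form was
chosen over the usual two tails of the case statistic because it is exactly
invariant to which group is called "case", a property we consider essential
for a symmetric question; it is conservative, as Bonferroni combinations
are. For n small enough that C(n, n_cases) is manageable, `exhaustive=True`
enumerates every arrangement and returns the exact proportion at least as
extreme (identity arrangement included), which the Monte-Carlo p converges
to as B grows.

Default B = 10,000 for analyses; the replicated calibration experiments use
B = 199, which makes the attainable p-values multiples of 1/200 so that the
α = 0.05 rejection probability under the null is exactly 0.05.

## Alpha diversity

Richness counts taxa with positive abundance. Shannon entropy is reported in
nats by default (base configurable). Chao1 uses the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)), stable when doubletons are absent, and refuses
non-integer input since singleton counts are meaningless on proportions.
Inverse Simpson is 1/Σpₖ². Faith's phylogenetic diversity is the total
branch length of the minimal rooted subtree spanning the observed taxa — the
"whole tree" variant that includes the path to the root — computed through
scikit-bio; the test suite validates it against a brute-force edge
enumeration. Alpha diversity is computed at the finest level of the input
table, as upstream OTU pipelines do.

## Taxon-wise screening and covariate models

Each taxon (pooled across every collapsed level, phylum through species, so
a family and its genera are tested as separate hypotheses) enters a logistic
regression of case status on its relative abundance plus age, sex and race.
Abundances enter untransformed by default; `transform="arcsin_sqrt"` is
available. The Wald z for the abundance coefficient gives the p-value;
Benjamini–Hochberg adjustment across all tested taxa gives q-values.
Per-variable (unadjusted) logistic models produce the covariate-association
table, one model per variable with dummy expansion against a declared
reference level.

All logistic fits use a binomial GLM via IRLS rather than a
Newton–Raphson ML routine that hard-fails on separation: empty cells (e.g. a
race level with zero cases) then surface as enormous standard errors and are
flagged, mirroring how standard `glm` output reports them, instead of
aborting a 2000-taxon screen. Zero-variance taxa are skipped with NaN rows.

The cluster-by-case test is a Pearson chi-square of independence on the K×2
table (df = K−1, no continuity correction).

## Synthetic data generator

`simulate_dataset` draws, per sample, a composition from a Dirichlet prior
and a multinomial read vector at exactly `depth` reads (default 10,000,
matching typical rarefaction depth). Overdispersion is governed by the total
concentration; the default concentration profile is lognormal (σ = 1)
normalised to a total of 50, because real gut communities are strongly
uneven — a symmetric Dirichlet is available by passing a scalar
`base_concentration`, and any positive vector is accepted. Case samples
multiply the concentrations of a randomly chosen `effect_taxa_fraction` of
taxa by `effect_size`; injecting the effect on concentrations (not post-hoc
means) keeps compositional renormalisation coherent, and `effect_size = 1`
makes the two groups exactly exchangeable — the null used for calibration.

Metadata mirrors an American-Gut style questionnaire: age ~ Normal(46, 16²)
clipped to [4, 99], BMI ~ Normal(24, 5²), sex, five race levels, eight
regions, diet/alcohol/smoking/antibiotic/weight-change vocabularies and
gluten/lactose/asthma flags at realistic population frequencies. The case
label is written to the exposure column and is assigned to exactly
`n_cases` samples by weighted sampling without replacement with weights
∝ exp(age_effect·age) (default −0.04 log-odds/year, so cases skew younger),
reconciling fixed group sizes with a logistic age link. Default samples all
pass the exclusion filters so that cleaning is exercised with hand-built
fixtures rather than by eroding simulated group sizes.

`simulate_tree` produces a rooted random binary topology by uniform joins
with Exponential(1) branch lengths — any positive-branch-length tree
suffices for PD testing; it makes no claim of phylogenetic realism.

What the simulator does **not** emulate: sequencing error and chimeras,
taxon–taxon correlation beyond the Dirichlet's negative compositional
correlation, zero inflation beyond multinomial sampling, batch effects, and
within-family (twin) dependence. Passing calibration and power checks on
these simulations therefore validates the statistical machinery, not the
biology of any particular real dataset.

## Replicated experiments and problem sizes

The self-validation experiments (in `microbiome_cc.experiments`, also run by
`scripts/acceptance.py`) use desk-scale study conditions chosen once:

- **Type-I error**: 500 null replicates (effect_size = 1), 20+20 samples,
  100 taxa, genus level, B = 199, α = 0.05; the rejection rate is judged
  against the binomial 95% band [0.032, 0.071].
- **Power / recovery**: 100 replicates with effect_size = 4 on 10% of 100
  taxa, 100+100 samples. Power is the rejection rate of the clustering test;
  recovery asks whether the bottom 5% of Wald p-values at the finest level
  are all ground-truth affected taxa. (All ten affected taxa cannot fit in
  five bottom-5% slots, so "affected taxa rank in the bottom 5%" is
  operationalised as the bottom slots being purely affected; the
  median-rank comparison between affected and unaffected taxa is asserted
  separately in the unit tests.)
- **FDR**: 500 replicates of m = 100 independent Uniform(0,1) null p-values
  through the BH step at α = 0.05; the mean false-discovery proportion must
  not exceed α + 2 Monte-Carlo SEs. Uniform nulls isolate the FDR step
  itself; the finite-sample calibration of the GLM p-values feeding it is
  tested separately (KS uniformity at n = 150).

## Numerical choices and degenerate inputs

- Relative rows must sum to 1 within 1e-9; collapse conserves sample totals
  to machine precision and is idempotent.
- Divergence matrices are symmetrised and clipped to [0, ln 2] after
  computation to absorb float round-off; the diagonal is exactly zero.
- Tie-breaking in agglomeration follows scipy's deterministic ordering;
  cutting uses `cut_tree(n_clusters=K)` so exactly K clusters result even
  under tied merge heights. Cluster letters are assigned by first appearance
  in sample order, so labels are stable across reruns.
- Average linkage on raw JSD is the default; Ward on √JSD (a metric) via
  `sqrt_transform=True`. K defaults to 4.
- Comparisons of permutation statistics use a 1e-12 slack so that exact ties
  count as "at least as extreme".
- Degenerate inputs fail loudly and early: all-zero samples, all-case or
  all-control label vectors, K > n, taxa missing from the tree, negative or
  ragged table rows (reported with their line numbers).

## Known limitations

- Exclusion-filter counts attribute each removed sample to the first rule it
  violates; datasets reported with overlapping per-filter counts will not
  match this accounting (the totals will).
- The permutation test conditions on the realised case-set size; it does not
  model sampling of exposure status.
- Hierarchical cluster boundaries are unstable in weakly structured data;
  the cluster-by-case chi-square inherits that instability and is best read
  as descriptive.
- No handling of paired/related samples (e.g. twins): all tests assume
  independent subjects.
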