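# Methods

## The analysis in brief

`crossome` implements cross-ome molecular fingerprinting for a matched
proteome + lipidome profiled across a genotype panel (a control line plus a
collection of mutants, each in replicate). The premise is that when a
perturbation co-regulates a set of proteins and a set of lipids, their
abundance profiles rise and fall together across the panel, so rank
correlation between layers exposes co-perturbed modules without assuming
linearity or a shared intensity scale. The chain is:

1. **Preprocess** each layer (optional per-sample median centering; a
   detection filter; no imputation anywhere).
2. **Correlate** every lipid against every protein with Kendall's tau-b,
   pairwise-complete over missing values.
3. **Filter** the matrix for connectivity: a feature survives only with at
   least `min_partners` cross-ome cells at `|tau|` strictly above
   `tau_threshold`.
4. **Cluster** both axes: hierarchical clustering (average linkage,
   Euclidean) supplies the heatmap/dendrogram ordering, k-means (k-means++,
   best of `restarts`, seeded) supplies the discrete assignments.
5. **Enrich** cluster members against annotation sets (GO CC for proteins,
   lipid classes parsed from shorthand names for lipids) with one-sided
   Fisher exact tests, BH-adjusted per layer and run.
6. **Summarise** downstream: per-genotype cluster/module signatures,
   bipartite network extraction, top-partner frequencies, rank-skew tests
   for lipid classes, chain-length profiles, and robust-z outlier calls.

## Kendall tau-b and the pair-sign formulation

For two profiles the statistic is

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)),

with C/D the concordant/discordant sample-pair counts, n0 = n(n-1)/2, and
n1, n2 the tied-pair counts of each profile. Missing data are handled
pairwise-complete: only samples observed in both features contribute to that
cell, and cells with fewer than `min_overlap` joint samples (default 12) are
reported missing — below roughly a dozen points tau is so coarsely quantised
that a 0.4 threshold is meaningless.

The full lipid x protein matrix is computed at once. For feature *f* define
over all sample pairs (i, j) the sign vector `S_f = sign(v_i - v_j)` (zero on
a tie or when either sample is missing) and the validity vector `V_f` (one
when both samples are observed). Then `C - D = S_L . S_P`,
`n0 - n1 = |S_L| . V_P` and `n0 - n2 = V_L . |S_P|`, so the whole matrix
reduces to three matrix products. This is exact — ties and missingness
included — and is verified in the tests against both an exhaustive all-pairs
oracle and `scipy.stats.kendalltau`, which are never used as the
implementation.

Memory grows with samples^2 per feature (pair space), which is comfortable
at panel scale (tens of samples, thousands of features) but would need
chunking for cohorts of many hundreds of samples.

## Connectivity filter

Retention is decided in a single pass against the full pre-filter matrix:
partner counts are never recomputed after removals, so a feature can keep a
partner that itself was dropped. The inequality at the threshold is strict
(`|tau| > 0.4`, not `>=`), and missing cells never count as partners. Both
choices are boundary-tested.

## Clustering

Feature vectors are tau profiles (proteins over retained lipids, lipids over
retained proteins). Missing tau cells are imputed as 0 — the
null-association value — for distance computations only; they remain missing
in every exported table. Features are put in a canonical (sorted) order
before seeding so assignments are invariant to input order. Defaults k = 18
(protein) and k = 13 (lipid) suit a landscape-scale knockout panel; a
14-cluster lipid cut is a common alternative and is one argument away.
Genotype grouping applies the same
k-means machinery to a genotypes x curated-set signature matrix.

## Enrichment and rank tests

Fisher p-values are the upper hypergeometric tail
`P(X >= a)` computed with `scipy.stats.hypergeom.sf`; the test suite pins
them to exact-fraction tail sums at relative error <= 1e-12 for backgrounds
up to 200. One-sided enrichment is used because depletion is consumed
nowhere downstream. The background is the set of features retained by the
connectivity filter in the tested layer — conditioning on entry into the
analysis — and the BH family is all (cluster, term) pairs of one layer in
one run. The rank-skew test ranks features by log2FC descending and applies
a one-sided Wilcoxon rank-sum for class members sitting high; the exact
null is used when min(group) <= 10 and N <= 30, otherwise the normal
approximation with continuity correction. Ties share average ranks.

## Fold changes and signatures

log2FC(feature, genotype) is the mean over the genotype's observed
replicates minus the mean over control's, computed on log2 values with no
imputation; a cell is missing unless both sides have `min_reps` (default 2
of quadruplicates — tolerant of one dropout, never a single-point fold
change) observations. Cluster signatures default to **sums** of member
log2FC (matching how correlation-cluster signatures are conventionally
displayed) and curated-module signatures to **means**; both are available
everywhere and the mode is recorded on every profile.

## Outlier analysis

Per feature, each genotype's log2FC is scored as
`z = (x - median) / (1.4826 * MAD + 1e-9)` across the panel, with a fallback
to the sample SD when the MAD is zero; `|z| >= 2.5` flags the genotype, and
features observed in fewer than `min_genotypes` (default 10) genotypes are
skipped. The criterion is a deliberately simple, documented robust-z rule
of this package's own design — there is no canonical definition of an
"outlier genotype" for panels like this — and every constant is exposed. For a flagged
genotype, the other genotypes are ranked by Pearson similarity computed over
the full tested feature block rather than only the flagged features — a
genotype flagged on a single feature would otherwise have an undefined
correlation.

## Lipid shorthand parsing

The grammar is the compact LipiDex-style dialect: a class token with an
optional bracket qualifier (`Cer[NS]`), then chains as `C:D` tokens joined by
`_` or `/` (treated identically; sn-position carries no information used
here). `O-`/`P-` prefixes set plasmanyl/plasmenyl ether type and are
rejected on non-glycerolipid classes; `d`/`t` prefixes record sphingoid
hydroxylation; `;`-suffixes on chains are tolerated but not interpreted.
Multi-chain names are `molecular` resolution, single-token names `species`
(sum composition). Unknown class tokens parse fine — class-level enrichment
is the only consumer — and unparseable names are binned as `unclassified`
rather than raised during bulk classification.

## The synthetic panel: what it emulates, and what it does not

`simulate_panel` emulates a knockout screen profiled in quadruplicate:
defaults are 12 mutants + control, 4 replicates, 600 proteins, 300 lipids,
and 5 planted modules (30 proteins + 15 lipids each) sharing a +1.5 log2
shift in 3 affected mutant genotypes, on a N(20, 3^2) log2 baseline with
N(0, 0.4^2) replicate noise. Missingness is 5% uniform plus an
intensity-dependent (MNAR) component
`p = max(0, 2*sigmoid(slope*(q10 - v)) - 1)` confined to the low-abundance
tail — continuous at the 10th percentile and monotone in abundance, which
the tests check on binned rates. Affected-genotype patterns are drawn
without replacement *and pairwise distinct across modules*: two modules with
the same affected set would be a single unidentifiable perturbation, and no
analysis could separate them. Lipid features carry parseable shorthand
names so the nomenclature machinery runs on simulated panels too.
Annotations ship as one term per planted module plus size-matched decoy
terms so enrichment FDR is meaningful.

Cross-ome correlation is *not* planted directly: it emerges from the shared
affected-genotype pattern, which is exactly the mechanism the pipeline is
supposed to detect, so recovery tests exercise the chain end to end.

What the generator does not emulate: acquisition-batch drift, lipid
co-regulation beyond block modules, heavy-tailed or intensity-dependent
noise, correlated replicate structure, or realistic lipid-class abundance
distributions. Passing recovery tests therefore demonstrates correctness of
the machinery under idealised block structure, not performance on instrument
data.

## Recovery evaluation and the problem sizes used

`evaluate_recovery` reports, per axis, the adjusted Rand index between
k-means assignments and planted module labels restricted to planted
features; the fraction of within-module lipid-protein tau values that are
positive; and the fraction of planted annotation terms reaching BH q < 0.05
in their best-matching cluster. Recovery runs cluster with
**k = n_modules + 1**: the connectivity filter legitimately retains a few
weakly structured background features, and reserving one cluster for them
prevents a forced merge of two true modules — the same logic by which a
real landscape is cut into many more clusters than it has headline modules.
The shipped checks sweep 10 generator seeds at the default panel size, which
keeps the whole recovery suite under a minute on one CPU; typical minima are
ARI >= 0.9 on both axes with all within-module taus positive.

## Numerical and degenerate-input choices

* Constant profiles, or fewer than 2 joint observations, give a missing tau
  (the tie-corrected denominator would be 0).
* Fisher p-values are clipped into (0, 1]; odds ratios with an empty
  off-diagonal cell are reported as infinity.
* k-means label ids are stable: raw labels are remapped to 1..k in order of
  first appearance over canonically sorted features.
* All TSV exports fix the float format (`%.10g`), making reruns
  byte-identical under fixed seeds.
* Empty results are contracts, not errors, where the analysis can genuinely
  produce them (an empty filtered matrix warns; an empty network is valid).

## Known limitations

* Replicate-level correlation (the default `profile_mode`) treats replicates
  as exchangeable panel points; genotype-mean mode is available but with 13
  profiles tau is coarse.
* No batch correction across acquisition sets and no QC-drift correction;
  matrices are assumed comparable after (optional) median centering.
* The GO graph is not propagated; terms are tested as flat sets.
* P-values for individual tau cells are deliberately not computed.
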