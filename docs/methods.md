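# Methods

This note documents the statistical procedures, their tunable parameters,
the synthetic data model used to exercise them, and the numerical and design
choices that were genuinely open.

## Preprocessing

Input matrices are raw counts (genes × cells on disk, MatrixMarket; cells ×
genes in memory, backed by AnnData).  QC keeps cells with a number of
detected genes (strictly positive count) between `min_features` (default
200) and `max_features` (2500, inclusive bounds) and genes detected in at
least `min_cells` (100) cells.  Filtering order is cells-then-genes by
default and configurable, since protocols differ and the result is
insensitive on our data.  With several cell lines in one matrix, the gene
filter counts detections within each line and keeps a gene passing in at
least one line (a per-line analysis never discards a gene another line
needs); a pooled mode is available.  Normalization is
ln(1 + count/total × scale) with scale 10⁴; the log base is configurable
and recorded in the output metadata.

## Consensus signatures (RRA)

Differential expression uses the two-sided Wilcoxon rank-sum test per gene
on log-normalized values, with log2 fold change computed on de-logged
(expm1) group means with pseudocount ε = 1, Bonferroni adjustment across
genes by default (BH available), and a deterministic sort: descending
log2FC, then ascending p, then gene id.

Robust Rank Aggregation scores a gene seen at normalized ranks
r₍₁₎ ≤ … ≤ r₍ₖ₎ across m lists with ρ = min_j P(Bin(m, r₍ⱼ₎) ≥ j).  A gene
absent from a list contributes no rank but m stays the total list count
(conservative for sporadic genes).  "Adjusted rank p" is taken in two
explicit stages: a Bonferroni factor m over the order statistics
(p = min(ρm, 1)) and then Benjamini–Hochberg across genes; either stage can
be switched off.  When the input lists are pre-filtered (e.g. only the
significantly upregulated genes of each experiment), positions are
normalized by `universe_size` — the number of genes originally tested —
rather than the filtered length; otherwise every member of a short filtered
list would look uniformly ranked and the aggregation would carry no signal.
Downregulated consensus signatures reuse the same machinery with the sign
of log2FC flipped.

The cross-species route uses majority voting (genes upregulated in at least
`min_support` of the per-experiment lists, default 5) followed by ortholog
mapping from a two-column table; one-to-many mappings contribute all
targets, unmapped genes are dropped and counted in a report.

## Activity scoring

The per-cell score of a gene set ranks all genes by descending expression
(ties broken by a seeded random permutation, so the score is invariant to
monotone transforms and reproducible) and computes the area under the step
curve y(x) = number of set genes among the top x ranks for
x = 1..R, R = ⌈0.05 × n_genes⌉, divided by the area of the ideal curve in
which all min(|set|, R) set genes occupy the top ranks.  The default
`max_rank_fraction` of 0.05 is the scoring method's documented default; it
is configurable and recorded.

The activity threshold builds a null from expression-matched controls: all
expressed genes are assigned to 10 equal-frequency bins by mean normalized
expression; one repeat draws, for each signature gene, a random non-signature
gene from its bin (nearest non-empty bin as fallback), scores all cells on
the control set, and keeps the 95th percentile; the final threshold is the
maximum over 100 repeats.  Taking the maximum makes the call deliberately
conservative — on matched-null signatures the measured active fraction is
about 1%, well under the 5% that a single 95th percentile would give.

Module scores subtract the mean of a bin-matched control pool
(`ctrl_per_gene` = 100 draws per signature gene, same 10 bins) from the mean
signature expression.  Cell-cycle phases are assigned by the highest module
score among the G0/G1/S/G2M signatures, with ties resolved by the fixed
priority order G0 < G1 < S < G2M (arbitrary but recorded in the output).

ssGSEA ranks a sample's genes by descending value and accumulates
(N − position + 1)^α weights (α = 0.25), normalized over set members,
against 1/(N − |set|) for non-members; the score is the sum of the running
difference.  No across-sample min–max rescaling is applied by default since
scores are only compared within one cohort; a rescaling flag exists.
Ranked-list GSEA uses the classic weighted Kolmogorov–Smirnov running sum
with weight |log2FC|, a gene-permutation null, NES = ES divided by the mean
|ES| of same-sign permutations, and a +1 pseudo-count tail p.

## RAC calling

Per cell line, each cluster's active/inactive counts form a 2×2 table
against all other clusters; the odds ratio is
(active_in/inactive_in)/(active_out/inactive_out) with ∞ and 0 boundaries
reported as flagged sentinels (no continuity correction by default), p from
the two-sided Fisher exact test (R-style definition), and BH adjustment
across that line's clusters (the protocol names only "adjusted p-value";
BH is the choice here and is logged).  A RAC requires strictly OR > 1 and
adjusted p < 0.05.  A RAC is *pre-existing* when the same test restricted
to untreated cells also flags it, *emergent* otherwise.  Drug-class
concentration in a set of member clusters uses the analogous 2×2 on treated
cells, built within each line and summed across lines.

The activity threshold is computed on pooled treated + untreated cells of a
line (whether the original analysis pooled is unstated; pooling is the
default and the split is configurable upstream).

## Superclusters

Per line, the dispersion statistic for variable-gene selection is the
variance of clipped standardized values: a quadratic trend of log10
variance vs log10 mean is fit across genes, values are standardized by the
trend-expected SD, clipped at √n_cells, and the residual variance ranks the
genes.  The shared gene list is the intersection of per-line top-n lists.
The genome-scale protocol uses n = 2000 (of ~25k genes); on the simulated
2000-gene universe the scaled default is n = 500 (similar selectivity) —
selecting the full universe would make this step a no-op and dilute the
cross-line correlations with unregulated genes.

Each cluster's differential mean vector (cluster mean minus same-line
complement mean over the shared genes) enters an all-by-all Spearman
matrix; average-linkage clustering on 1 − ρ is cut at height 0.7 (no
linkage or cut is named in the protocol; average linkage is the common
default for correlation grouping, and the full linkage record is always
emitted so alternative cuts are reproducible).  A group qualifies as a
supercluster when its RAC members span ≥ `min_lines` distinct cell lines;
the default is 2 — the source analysis is ambiguous between "two" and "all
three" lines, and the stricter reading is available via `min_lines=3`.
Non-RAC clusters participate in the correlation matrix but are never
assigned to superclusters.  Supercluster consensus signatures run RRA over
the component RACs' DE lists (each RAC vs all same-line non-RAC cells),
filtered to the requested direction, with `universe_size` equal to the
unfiltered list length.

## Enrichment

Over-representation is the upper-tail hypergeometric probability
P(X ≥ k) for an overlap of k between query (n genes in universe) and
collection set (K in universe, universe N), BH-corrected within one
collection (not pooled across collections).  The default universe is all
genes expressed in the relevant matrix; a collection-defined universe is
available.

## Clinical stage

The Cox model maximizes the Efron-tie partial likelihood by Newton
iterations on standardized covariates to gradient norm < 1e-8, reports
per-covariate hazard ratios, Wald tests and 95% CIs, and raises on constant
covariates and on monotone likelihoods (estimates diverging past ‖β‖ > 50).
Samples with missing covariates are dropped listwise with a logged count.
Median splits assign scores strictly above the median to "high" and ties at
the median to "low" (deterministic; group sizes are always reported).
Cohort-level pooling of hazard ratios uses a one-sample t-test on log HR.
Binary-outcome comparisons report the higher-scoring group, the two-sided
rank-sum p (exact by enumeration for combined n ≤ 20, tie-corrected normal
approximation otherwise) and Cohen's d with (n−1)-weighted pooled SD.

## Synthetic data model

`simulate_cell_lines` draws counts from a negative binomial with gene-level
log-normal baseline means (meanlog −1, sdlog 1, giving ~1200 counts and
~600 detected genes per cell at the 2000-gene default) and dispersion 0.3
(variance = μ + 0.3μ²).  Each cluster receives a small gene-wise log-normal
jitter (sd 0.1) so that clusters are distinguishable but uncorrelated across
lines; only the planted programs (two disjoint 100-gene sets, means × fold 4
in one designated cluster per program per line) correlate across lines.
80% of cells are treated; treated cells in active clusters draw the
concentrated drug class with probability 0.9 (0.05 elsewhere), which places
≥ 80% of that class's cells in active clusters.  `simulate_ranked_lists`
plants consensus genes uniformly within the top 5% of each list.
`simulate_survival_cohort` shifts signature-gene expression by a per-sample
activity a ~ N(0,1), defines the planted score as the z-scored mean
signature expression, and draws event times exponentially with hazard
h₀·exp(β·score), h₀ = 0.1, with independent censoring and
hazard-independent age/sex/purity covariates.

What the simulation does not model: library-size and batch variation,
doublets, ambient RNA, gene–gene correlation beyond the planted programs,
and non-proportional hazards.  Passing tests therefore demonstrate that the
procedures recover the structures they target under their stated noise
model, not performance on real data.

## Problem sizes used in tests

The default study design mirrors a small multi-line screen: 3 lines × 8
clusters × 200 cells, 2000 genes, two 100-gene programs at fold 4.
Recovery tests aggregate 20 simulation seeds for RAC calling, 3 for the
supercluster stage, 20/50/20 for the clinical-stage checks; null
calibrations use 20 seeds (activity), one 600-cell split across 2000 genes
(DE type I) and 200 random sets × 200 permutations (GSEA uniformity).

## Known limitations

Exact Wilcoxon enumeration is O(C(n, n₁)) and limited to combined n ≤ 20.
The Cox solver is dense O(n²p) per iteration — fine for cohort sizes here,
not for biobank scale.  RRA assumes independent lists; correlated component
RACs (shared background cells within a line) make the consensus slightly
anti-conservative, which is why the acceptance checks measure recall against
planted truth rather than nominal error rates.  The AUCell-style score
saturates when |signature| ≫ R; signatures larger than the rank window are
scored on their best R genes.
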