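# resistsig

Detection of drug-resistance-associated transcriptional states in early
drug-response single-cell RNA-seq data.

When cancer cell lines are exposed to a drug for a short time, a subset of
transcriptional clusters up-regulates gene programs that resemble the
signatures of cells that ultimately survive long-term treatment.  This
package implements, as a tested and fully simulatable pipeline, the chain of
analyses needed to find and validate those states:

1. **Consensus resistance signature.**  Per-experiment ranked
   differential-expression lists (Wilcoxon rank-sum on log-normalized
   values, genes with log2FC > 0 and adjusted p < 0.05) are combined with
   Robust Rank Aggregation: each gene is scored
   ρ = min_j P(Binomial(m, r₍ⱼ₎) ≥ j), the smallest binomial tail
   probability of its j-th best normalized rank r₍ⱼ₎ across m lists under
   uniform ranks; genes with adjusted rank p < 0.05 form the signature.
2. **Per-cell activity (AUCell-style).**  Genes are ranked within each cell
   by descending expression and the signature score is the area under the
   recovery curve of signature genes among the top 5% of ranks, normalized
   by the ideal curve.  A cell is *active* when its score exceeds a null
   threshold: the maximum, over 100 draws of expression-decile-matched
   control gene sets, of the 95th percentile of control-set scores.
3. **Resistance-Activated Clusters (RACs).**  Within each cell line, each
   cluster's active/inactive counts are compared against all other clusters
   in a 2×2 Fisher exact test; clusters with odds ratio > 1 and
   BH-adjusted p < 0.05 are RACs, further labelled pre-existing or emergent
   depending on whether untreated cells alone reproduce the call.
4. **Superclusters.**  RACs are matched across cell lines by hierarchically
   clustering (average linkage, 1 − ρ distance) the Spearman correlations of
   their differential mean-expression vectors over shared highly variable
   genes; correlated groups spanning ≥ 2 lines become superclusters, with
   consensus signatures re-derived by RRA over the component RACs' DE lists.
5. **Enrichment and cross-species mapping.**  Hypergeometric
   over-representation of signatures against gene-set collections (GMT), and
   ortholog-table mapping of signatures between species.
6. **Clinical validation.**  Bulk cohorts are scored per sample with ssGSEA;
   survival association is estimated with a Cox proportional-hazards model
   (Newton iterations on the Efron partial likelihood) controlling for age,
   sex and tumor purity, with median-split Kaplan–Meier groups and
   rank-sum/Cohen's d comparisons for binary outcomes.

No external accession is required: the `synthetic_data` module generates
every input with recorded ground truth — negative-binomial count matrices
with planted fold-4 gene programs in designated clusters, ranked lists with
a planted consensus set, and survival cohorts whose hazard is exponential in
a planted signature score — so every downstream claim is checked against a
known answer.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic design (3 cell lines × 8 clusters × 200 cells, 2000 genes, two
100-gene programs at fold 4, seed 1) and write their tables under
`results/tables/`:

```bash
cd analysis
python 01_simulate_inputs.py
python 05_call_racs.py
python 08_clinical_validation.py
```

prints (abridged):

```
planted active clusters: ['LINE1_c4', 'LINE1_c7', 'LINE2_c1', 'LINE2_c3', 'LINE3_c0', 'LINE3_c7']
...
RACs called: ['LINE1_c4', 'LINE1_c7', 'LINE2_c1', 'LINE2_c3', 'LINE3_c0', 'LINE3_c7']
sensitivity vs planted clusters: 100.0%  (0 false-positive clusters)
most concentrated drug class in RACs: hdac_inhibitor (OR 168.6, adj p 0.00e+00; planted: hdac_inhibitor)
...
planted log-hazard coefficient: 1.0
fitted: beta 1.135, HR 3.11 (95% CI 2.68-3.60), p 1.12e-51
median split: 250 high vs 250 low, log-rank p 1.85e-36
```

i.e. the six planted clusters are recovered exactly, the drug class seeded
into the active clusters is the one found concentrated there, and the Cox
fit recovers the planted hazard coefficient (β = 1) within its confidence
interval.  The same run can be driven from a single entry point:

```bash
resistsig run --seed 1 --out-dir results/run
```

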