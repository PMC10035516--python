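# anchorsig

Anchor-gene mesenchymal signature workflows for bulk expression cohorts.

Bulk tumor cohorts — for example colorectal cancer liver metastases profiled
on expression arrays — often hide a mesenchymal (EMT-like) subgroup with a
distinct immune phenotype. `anchorsig` implements the intrinsic-signature
workflow that finds it without external training data:

1. **Anchor selection** — among candidate EMT transcription factors (ZEB1,
   ZEB2, SNAI1, SNAI2, TWIST1, TWIST2, PRRX1), pick the one with the highest
   expression variance across the cohort.
2. **Contrast groups** — rank samples by anchor expression and take the top
   and bottom quantile (default 25%) restricted to unique patients.
3. **SAM differential expression** — per gene, the relative difference
   `d = (x̄_high − x̄_low)/(s + s₀)` with a permutation null over group
   labelings; the estimated FDR at threshold `t` is
   `median_b #{|d*_b| ≥ t} / #{|d| ≥ t}`, and genes at q ≤ 0.001 form the
   signature, split by fold-change direction.
4. **Scoring and stratification** — the signature score of a sample is the
   mean log2 expression of the upregulated signature genes; UPGMA
   (average-linkage, Euclidean) clustering on the signature genes defines
   two major clusters and four dendrogram subgroups (high / int1 / int2 /
   low), with undersized outlier subbranches dissolved into the subgroup
   whose score range contains them.
5. **Immune profiling** — Pearson correlation of the score with immune
   checkpoint and macrophage markers (HAVCR2/TIM-3, VISTA, CTLA4, TIGIT,
   CD276, CD163, NOS2), subgroup comparisons (ANOVA / t-test / Fisher's
   exact), hypergeometric gene-set enrichment and exact Venn overlap.
6. **Transfer** — intersect the signature with an external cohort's genes,
   re-cluster on the matched genes, and report the Cluster-1 proportion and
   the recomputed score–marker correlations.

A synthetic-cohort generator with planted ground truth (latent mesenchymal
factor, co-expressed signature block, patient lesion pairs, calibrated
checkpoint correlations) backs every stage with recoverable truth; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
from anchorsig import SyntheticCohortConfig, generate_cohort
from anchorsig.pipeline import run_discovery

matrix, truth = generate_cohort(SyntheticCohortConfig(seed=10))
res = run_discovery(matrix, seed=10)

print(res.anchor_report.selected_anchor)       # PRRX1
print(dict(res.anchor_report.variances.round(2)))
# {'PRRX1': 12.22, 'TWIST1': 1.24, 'ZEB1': 1.1, 'TWIST2': 1.03,
#  'SNAI1': 1.02, 'ZEB2': 0.91, 'SNAI2': 0.54}
print(len(res.signature.up_genes), len(res.signature.down_genes))
# 238 1   (genes at SAM q <= 0.001, s0 = 0.583, 1000 labelings)
print(res.assignment.subgroup.value_counts().to_dict())
# {'low': 24, 'int1': 8, 'high': 6}
print(res.correlations.table.round(3))
#              r  p_value  q_bh   n
# CD163    0.908      0.0   0.0  38
# HAVCR2   0.766      0.0   0.0  38
# TIGIT    0.714      0.0   0.0  38
# VISTA    0.546      0.0   0.0  38
# CTLA4    0.546      0.0   0.0  38
```

The anchor dominates the decoy factors by variance; 239 of the 400 planted
signature genes clear the strict FDR cut with no background genes admitted;
the six "high"-subgroup samples are exactly the planted high samples (their
mean score is 10.45 versus 7.41 in the "low" subgroup, log2 units); and the
recovered checkpoint correlations sit near their planted targets (HAVCR2
0.77 vs 0.83, CD163 0.91 vs 0.86) with the attenuation expected at n = 38.
Two outlier samples were absorbed into the high subgroup by the score-range
rule, each with an audit record in `res.assignment.merged_outliers`.

Real cohorts enter the same way: `read_expression_table` (TSV or GEO
series-matrix dialect), `quantile_normalize_log2`, and
`collapse_probes_to_genes` produce the `ExpressionMatrix` that
`run_discovery` consumes, and `validate_on_cohort` transfers a signature to
any other cohort (`scripts/fetch_geo.py` downloads the series matrices of
the usual validation accessions; nothing in the tests needs the network).

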