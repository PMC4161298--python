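# dispca

Exploring shared pathogenetics across GWAS datasets with principal
component analysis of gene-level association statistics.

Many diseases share genetic risk factors (pleiotropy), but most
cross-phenotype methods either require genotype-level data or focus on one
variant or one disease pair at a time. `dispca` works from per-study
**summary statistics** only. It converts SNP association p-values into
gene-level empirical p-values, assembles a datasets × genes matrix of
−log10 p, removes study-level confounders by regression, and applies
PCA/SVD so that each principal component is a weighted combination of all
genes that maximally separates the studies. Datasets that share
pathogenetics lie close together in PC space; the genes with the largest
absolute loadings are the ones driving the separation. It is aimed at
statistical geneticists who have a shelf of heterogeneous GWAS summary
files and want a global, hypothesis-free map of which diseases overlap
genetically and through which genes.

## Method

1. **Gene scores.** Every SNP is mapped to the gene it falls in or the
   nearest gene within 0.01 cM (or 10 kb in physical mode); unmapped SNPs
   are discarded. A gene's statistic combines its n SNP p-values (minimum
   p by default; truncated product and truncated tail strength are also
   available). Significance is calibrated empirically against 100,000
   random runs of n consecutive SNPs: the gene's empirical p-value is the
   proportion of runs strictly more significant than the observed
   statistic (with a +1/+1 pseudocount so p ≥ 1/(N+1) and −log10 p stays
   finite).
2. **Matrix and confounders.** With d datasets and the g genes present in
   all of them, Z is the d × g matrix of −log10 empirical p-values. Each
   gene's cross-dataset vector z_i is regressed on the genotyping array,
   the association method (one-hot) and log10 sample size; per-coefficient
   t-tests flag confounder-associated genes (Bonferroni across genes), and
   the residual matrix R replaces Z.
3. **PCA.** Columns are mean-centered (no variance scaling) and the SVD
   B = U S Wᵀ is taken. Eigenvalues of the row covariance B Bᵀ equal the
   squared singular values; dataset coordinates are B W; gene loadings are
   the columns of W. Regressing out c independent covariates leaves
   exactly c extra zero-variance components beyond the one induced by
   centering.
4. **Clustering and cross-disease tests.** Datasets are clustered
   agglomeratively (complete linkage) on Euclidean distances over the
   first two PCs. Separately, for an ordered disease pair, the k genes
   with source p < 0.01 (optionally thinned so no two retained genes are
   within 0.1 cM) are combined in the target with Fisher's method,
   T = −2 Σ ln p_i ~ χ²(2k), testing a uniform target distribution.

A simulator generates both the gene-level pleiotropy design used to
validate the method (two disease classes of five diseases, 10,000 genes,
planted gene sets with p ~ U(0, 0.05)) and complete SNP-level inputs
(summary statistics, BED annotation, genetic map, covariates), so the
whole pipeline runs with no external data.

## Worked example

```python
import numpy as np
from dispca import (SimulationDesign, simulate_pleiotropy_matrix,
                    dispca_cluster, expected_groups, grouping_correct)

design = SimulationDesign(set2_size=60, set3_size=60, seed=1)
P, truth = simulate_pleiotropy_matrix(design)   # 10 diseases x 10,000 genes
pca, tree = dispca_cluster(P)                   # -log10, center, SVD, cluster

print("variance fractions:", np.round(pca.variance_fraction[:4], 3))
print("4-way cut:", sorted(sorted(g) for g in tree.cut(4)))
print("recovered:", grouping_correct(tree, expected_groups(design)))
```

prints

```
variance fractions: [0.125 0.122 0.113 0.111]
4-way cut: [['A1', 'A2'], ['A3', 'A4', 'A5'], ['B1', 'B2'], ['B3', 'B4', 'B5']]
recovered: True
```

The two leading PCs carry slightly more variance than the rest (the two
planted signal directions), and cutting the dendrogram into four clusters
recovers exactly the planted structure: the cross-class pleiotropic
quartet split into its class-A and class-B halves ({A1,A2} and {B1,B2})
and the two class backgrounds. `tree.to_newick()` exports the dendrogram
with Euclidean merge heights as branch lengths.

The same analysis is available from the shell for on-disk inputs:

```bash
dispca simulate --outdir sim --n-datasets 4 --seed 0
dispca score-genes --stats sim/DS1.assoc --genes sim/genes.bed \
    --genetic-map sim/genetic_map.txt --out DS1.scores.tsv
# ... score the remaining datasets ...
dispca build-matrix --scores DS1.scores.tsv --scores DS2.scores.tsv \
    --scores DS3.scores.tsv --scores DS4.scores.tsv \
    --covariates sim/covariates.tsv --out matrix.tsv
dispca dispca --matrix matrix.tsv --outdir out/
dispca crosstest --scores DS1.scores.tsv --scores DS2.scores.tsv --out fisher.tsv
```

`out/` then holds dataset coordinates, gene loadings, the variance table,
the dendrogram (Newick + merge table), top-loading gene lists and a GSEA
pre-ranked `.rnk` export.

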