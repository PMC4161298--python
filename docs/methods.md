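# Methods

## Model and procedure

`dispca` treats each GWAS dataset as one observation in the space of all
genes. The quantity analyzed is the strength of gene-disease association,
encoded as −log10 of a gene-level empirical p-value, so the analysis is
comparable across studies that differ in genotyping array, association
test and sample size.

### Gene-level empirical p-values

SNPs are assigned to genes by distance: a SNP inside a gene body belongs
to it; otherwise it goes to the nearest gene within the window (0.01 cM in
genetic mode, 10 kb in physical mode), and is discarded beyond that.
Distance to a gene is zero inside the body and the distance to the nearer
boundary outside it; gene cM boundaries are obtained by interpolating the
genetic map at the gene's bp endpoints. Exact distance ties go to the gene
with the smaller start coordinate, then lexicographic id; a SNP inside two
overlapping bodies goes to the gene with the nearer midpoint. These
tie-breaks carry no statistical weight — they only make output
deterministic across platforms.

A gene with n mapped SNPs receives a combination statistic: the minimum
SNP p-value (default), the truncated product (product of all p ≤ τ), or
the truncated tail strength ((1/k)·Σ_{p_(j)≤τ} (1 − p_(j)(k+1)/j), larger
more significant). τ defaults to 0.05. The statistic is calibrated against
an empirical null of N random runs of n consecutive SNPs drawn uniformly
over all within-chromosome start positions (runs never span chromosome
junctions, which would create artificial SNP groups). The gene's empirical
p-value is

    p = (1 + #{null runs strictly more significant than observed}) / (N + 1).

Two choices deserve note. The comparison is **strict**: a null run that
exactly ties the observed statistic — in particular a run containing the
gene's own best SNP, which the genome-wide sampling does not exclude —
does not count against the gene. And the +1/+1 **pseudocount** bounds p
in [1/(N+1), 1], keeping −log10 p finite for genes that beat every null
run; without it a raw proportion of zero would propagate an infinity into
the matrix. N defaults to 100,000; the calibration suites use N in the
hundreds to low thousands, which is ample for testing uniformity. One
null sample is drawn per distinct n and shared by all genes with that n:
the null depends on n only, and sharing makes a dataset's scores
reproducible and cheap (seeds are recorded in the output).

Because consecutive-SNP runs inherit local linkage disequilibrium, the
null is conservative in high-LD regions; this affects every dataset for a
given gene equally and therefore largely cancels in the cross-dataset
analysis. The physical-distance mode exists to check this: scores from
both modes can be compared on the same data (the CLI test suite does
exactly that on synthetic data).

### Matrix, confounders, PCA

Z is the d × g matrix of −log10 empirical p-values over the genes common
to all datasets (columns sorted by gene id, rows in input order). Each
gene's cross-dataset vector is regressed by OLS on an intercept, one-hot
encodings of array and method (first level as reference), and log10
sample size. Two-sided t-tests per coefficient with Bonferroni correction
across genes (per covariate, α = 0.05) flag confounder-associated genes.
The residual matrix R = (I − H)Z, H the hat matrix of that design, has
every column orthogonal to every design column; since the intercept is in
the design, R is also column-centered.

PCA is the SVD of the column-centered matrix with no variance scaling:
B = U S Wᵀ. Eigenvalues are the squared singular values and equal the
eigenvalues of B Bᵀ; "dataset coordinates" (what is plotted and
clustered) are B W = U S; gene loadings are the columns of W. Component
signs are fixed by making each component's largest-magnitude loading
positive, so results do not depend on the linear-algebra backend.
Residualizing on c linearly independent non-constant covariates removes c
directions from the row space, so exactly c components beyond the single
centering-induced one have zero eigenvalue — a built-in check that the
regression did what it should (asserted at 1e-10 of the leading
eigenvalue in the tests).

Gene rankings use the mean absolute loading over the selected components;
ranked lists can be thinned so that no two retained genes on one
chromosome are within 0.1 cM (scanning in genomic order and dropping the
latter gene of each close pair), which guards downstream enrichment
against clusters of linked genes. Replication is quantified by selecting
the k = 50 genes with the largest mean absolute loading across two
analyses, aligning component signs by inner product, and taking one
Pearson correlation over the concatenated per-component loading vectors
(two-sided p from the t distribution).

### Clustering and the cross-disease test

Datasets are clustered agglomeratively on Euclidean distances over the
first two coordinate columns. The agglomeration is done in-package
(complete linkage by default — the default of the classic hclust
implementation — with single and average available) with a deterministic
tie rule: among equally distant candidate pairs, merge the one with the
smallest cluster-id pair. Trees serialize to Newick with branch lengths
equal to merge-height differences. For n in the tens the naive O(n³)
algorithm is instantaneous, and the test suite checks it against an
independent library implementation on random instances.

The directed cross-disease test selects the k genes with source empirical
p strictly below 0.01 (optionally 0.1 cM-thinned) and combines their
target p-values with Fisher's method, T = −2 Σ ln p_i against χ²(2k).
Gene-level p-values are bounded below by the pseudocount, so ln p is
always finite. With k = 0 the pair is reported untestable rather than
given a p-value. Fisher's method assumes independent p-values; the
pruned variant exists precisely because nearby genes violate that.

## The simulator

The gene-level design draws a 10 × 10,000 p-value matrix for two disease
classes of five diseases (A1..A5, B1..B5): background genes U(0,1)
everywhere; one set of genes U(0, 0.05) in all class-A diseases
(within-class pleiotropy); a disjoint equal-size set U(0, 0.05) in
A1, A2, B1, B2 (cross-class pleiotropy). Both sets default to 40 genes.
This generator reproduces the validation conditions exactly as stated:
independent draws per disease, no correlation beyond the planted mean
shifts, no LD, no effect sizes. Consequently, passing tests demonstrate
that the linear-algebra pipeline recovers planted mean-shift structure at
the stated signal-to-noise ratio — they say nothing about LD-induced
correlation between genes or about confounding, which real data have and
which the SNP-level generator and confounder machinery address
separately.

"Correct grouping" for a replicate is operationalized as: cutting the
dendrogram into four clusters yields exactly {A1,A2}, {B1,B2},
{A3,A4,A5}, {B3,B4,B5}. This encodes both planted structures — one PC
direction isolates the cross-class quartet, the other separates the
classes — as a single binary, testable criterion.

### Recovery rates versus visual clarity

The recovery rate of this criterion (50–200 replicates per size, complete
linkage) is ~0 at 10–20 planted genes per set, ~0.1 at 30, ~0.5 at 40,
~0.95 at 60 and 1.0 from 80 upward. The figure-level behaviour — no
structure at 10, structure "emerging" around 30, clean separation in a
favourable draw at 40, tight clusters at 100+ — matches this curve, but a
single displayed replicate at 40 genes sits in a regime where roughly
half of the draws show textbook separation and half misplace one dataset.
The reason is quantitative: each planted set of m genes adds a spiked
eigenvalue of about m·(Δ/2)²·d ≈ 169 (at m = 40, mean shift
Δ = log10(20) ≈ 1.301, d = 10) to a Marchenko–Pastur noise bulk whose
top eigenvalue is σ²(√g + √d)² ≈ 2007 (σ = log10 e ≈ 0.434, g = 10⁴).
At m = 40 the sample spike (~2078) barely clears the noise edge, so the
signal directions are recovered only partially and occasionally drop
below PC2. From m ≈ 60 the spikes separate cleanly and recovery is
near-certain. The acceptance experiment therefore reports the smallest
set size at which ≥ 90% of 50 replicates are recovered, scanning
10–40 first and extending upward until the threshold is found (≈ 60
under these conditions). This was verified against an independent
implementation: on identical simulated matrices, R's prcomp reproduces
the dataset coordinates to 1e-13 and R's hclust the identical merge tree.

The SNP-level generator tiles chromosomes with evenly spaced SNPs
(default 5 kb), non-overlapping 20 kb genes every 50 kb, and a linear
1 cM/Mb genetic map; planted associated genes draw their SNP p-values
from U(0, 0.05) and everything else from U(0,1). It emulates the input
*formats* and the planted-signal logic end to end, not LD structure or
realistic marker density.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| mapping window (genetic) | 0.01 | cM | assignment radius around gene bodies |
| mapping window (physical) | 10,000 | bp | physical-mode equivalent |
| null size N | 100,000 | runs | resolution of empirical p (floor 1/(N+1)) |
| τ (truncated methods) | 0.05 | p-value | truncation point; nominal significance |
| selection threshold | 0.01 | p-value | source-gene selection, cross-disease test |
| pruning distance | 0.1 | cM | LD guard for ranked lists / Fisher input |
| linkage | complete | — | classic hclust default |
| n PCs for clustering | 2 | — | the two leading signal directions |
| confounder α | 0.05 | — | Bonferroni across genes per covariate |

## Numerical and degenerate-input choices

Genetic-map queries outside the mapped range clamp to the boundary cM
value rather than extrapolating (no negative or runaway positions at
chromosome ends); within the range interpolation is linear, an explicit
modelling choice since no finer information is available. SNP p-values
must lie in (0, 1]; exact zeros are rejected on input because −log10
must stay finite. The truncated product is evaluated in log space to
avoid underflow for large n. An empty truncation selection returns 1.0
(no evidence). Rank-deficient confounder designs are rejected with the
collinear columns named; designs need fewer columns than datasets.
Constant covariate columns are dropped by the one-hot encoding (a single
level encodes to nothing), so an intercept-only design reduces
residualization to column centering.

## Known limitations

The empirical null inherits LD structure from consecutive-SNP sampling
and is only exchangeable across datasets, not exact per gene. The
gene-level simulation contains no LD, so the pruning machinery is
exercised structurally rather than validated against realistic linkage.
Fisher's method over selected genes assumes independence even after
0.1 cM thinning. Hierarchical clustering on two PCs is a summary device:
with more than two planted structures, or signal spread over later
components, the two-PC distance underrepresents the geometry. The HLA
region filter uses a fixed default interval (chr6:25–35 Mb) that should
be adjusted to the annotation in use.
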