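"""Dataset x gene score matrix, confounder regression, and centered SVD/PCA.

The score matrix ``Z`` (d datasets x g genes) holds ``-log10`` gene-level
empirical p-values for the genes shared by all input datasets. Study-level
confounders -- genotyping array, association method (categorical, one-hot
with the first level as reference) and ``log10`` sample size -- can be
tested per gene by ordinary least squares and regressed out, producing a
residualized matrix ``R`` of the same shape. PCA is the singular value
decomposition of the column-centered matrix with no variance scaling:
eigenvalues of the d x d row covariance equal the squared singular values,
gene loadings are the right singular vectors, and dataset coordinates
(scores) are the centered rows projected onto them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError

#: default excluded region when HLA filtering is requested (chrom, start, end bp)
HLA_REGION = ("6", 25_000_000, 35_000_000)


@dataclass
class ScoreMatrix:
    """d x g matrix of -log10 gene-level empirical p-values plus row covariates."""

    Z: np.ndarray
    dataset_ids: list[str]
    gene_ids: list[str]
    covariates: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (len(self.dataset_ids), len(self.gene_ids)):
            raise ValidationError("score matrix shape does not match id lists")
        if not np.all(np.isfinite(self.Z)):
            raise ValidationError("score matrix entries must be finite")


@dataclass
class PcaResult:
    """Centered, unscaled SVD of a dataset x gene matrix.

    ``dataset_coords`` are the scores (centered rows times ``gene_loadings``),
    ``gene_loadings`` the right singular vectors (columns unit norm,
    orthogonal), ``eigenvalues`` the squared singular values in nonincreasing
    order, and ``variance_fraction`` their shares of the total.
    """

    dataset_ids: list[str]
    gene_ids: list[str]
    dataset_coords: np.ndarray
    gene_loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    left_vectors: np.ndarray
    source: str = "raw"


@dataclass
class ConfounderReport:
    """Per-gene OLS against the study covariates.

    ``coefficients`` and ``p_values`` are genes x encoded-covariate frames;
    ``significant`` flags Bonferroni-corrected significance per covariate
    column across genes at level ``alpha``.
    """

    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def build_matrix(tables, covariates: pd.DataFrame | None = None) -> ScoreMatrix:
    """Assemble the dataset x gene -log10 p matrix from gene-score tables.

    Gene columns are the intersection of the tables' gene sets, sorted by
    gene id; rows follow the input table order.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValidationError("need at least two gene-score tables")
    shared = set(tables[0].table["gene_id"])
    for t in tables[1:]:
        shared &= set(t.table["gene_id"])
    if not shared:
        raise ValidationError("no gene overlaps all datasets")
    gene_ids = sorted(shared)
    dataset_ids = [t.dataset_id for t in tables]
    if covariates is not None:
        missing = set(dataset_ids) - set(covariates["dataset_id"])
        if missing:
            raise ValidationError(f"datasets missing covariates: {sorted(missing)}")
        covariates = (
            covariates.set_index("dataset_id").loc[dataset_ids].reset_index()
        )
    Z = np.empty((len(tables), len(gene_ids)))
    for i, t in enumerate(tables):
        Z[i] = -np.log10(t.p_series().loc[gene_ids].to_numpy(dtype=float))
    return ScoreMatrix(Z=Z, dataset_ids=dataset_ids, gene_ids=gene_ids,
                       covariates=covariates)


def center_columns(Z: np.ndarray) -> np.ndarray:
    """Subtract each column's mean (the centering step before SVD)."""
    Z = np.asarray(Z, dtype=float)
    return Z - Z.mean(axis=0, keepdims=True)


def encode_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + one-hot array/method (first level reference) + log10 n."""
    d = len(covariates)
    cols = {"intercept": np.ones(d)}
    for name in ("array", "method"):
        if name in covariates.columns:
            levels = pd.unique(covariates[name])
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (covariates[name] == lev).to_numpy(float)
    if "n" in covariates.columns:
        cols["log10_n"] = np.log10(covariates["n"].to_numpy(dtype=float))
    return pd.DataFrame(cols)


def _design_matrix(matrix: ScoreMatrix, design: pd.DataFrame | None) -> pd.DataFrame:
    if design is None:
        if matrix.covariates is None:
            raise ConfigurationError("no covariates available")
        design = encode_design(matrix.covariates)
    d, p = design.shape
    if p >= d:
        raise ConfigurationError(
            f"design has {p} columns but only {d} datasets; cannot fit"
        )
    rank = np.linalg.matrix_rank(design.to_numpy(dtype=float))
    if rank < p:
        # name the columns involved in the collinearity for the error message
        X = design.to_numpy(dtype=float)
        bad = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(design.columns[j])
        raise ConfigurationError(f"rank-deficient design; collinear columns: {bad}")
    return design


def _ols(X: np.ndarray, Z: np.ndarray):
    """Vectorized OLS of every column of Z on X. Returns beta, resid, se, dof."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Z                      # p x g
    resid = Z - X @ beta                          # d x g
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / dof       # g
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return beta, resid, se, dof


def test_confounders(
    matrix: ScoreMatrix, alpha: float = 0.05, design: pd.DataFrame | None = None
) -> ConfounderReport:
    """OLS of every gene's cross-dataset vector on the encoded covariates.

    Two-sided t-test per coefficient; Bonferroni across genes within each
    covariate column at level *alpha*.
    """
    design = _design_matrix(matrix, design)
    X = design.to_numpy(dtype=float)
    beta, _, se, dof = _ols(X, matrix.Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    g = len(matrix.gene_ids)
    cols = [c for c in design.columns if c != "intercept"]
    keep = [design.columns.get_loc(c) for c in cols]
    coef = pd.DataFrame(beta[keep].T, index=matrix.gene_ids, columns=cols)
    pv = pd.DataFrame(pvals[keep].T, index=matrix.gene_ids, columns=cols)
    flags = pv < alpha / g
    return ConfounderReport(coefficients=coef, p_values=pv, significant=flags, alpha=alpha)


def residualize(matrix: ScoreMatrix, design: pd.DataFrame | None = None) -> np.ndarray:
    """Replace each gene column by its OLS residuals on the covariates.

    The returned matrix R has the same d x g shape as Z and every column is
    orthogonal to every design column (including the intercept, so R is also
    column-centered).
    """
    design = _design_matrix(matrix, design)
    X = design.to_numpy(dtype=float)
    _, resid, _, _ = _ols(X, matrix.Z)
    return resid


def run_pca(
    M: np.ndarray,
    dataset_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
    source: str = "raw",
) -> PcaResult:
    """Centered, unscaled PCA via SVD.

    Columns are centered (a no-op if *M* is already residualized with an
    intercept), then ``B = U S Wt``; eigenvalues are ``S**2``, gene loadings
    the rows of ``Wt`` transposed, and dataset coordinates ``B @ W``. The sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValidationError("matrix entries must be finite")
    d, g = M.shape
    if d < 2 or g < 1:
        raise ValidationError("need at least 2 rows and 1 column")
    B = center_columns(M)
    U, s, Wt = np.linalg.svd(B, full_matrices=False)
    W = Wt.T                                       # g x k loadings
    # deterministic sign: largest |loading| positive in every component
    for j in range(W.shape[1]):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
            U[:, j] = -U[:, j]
    eig = s**2
    total = eig.sum()
    frac = eig / total if total > 0 else np.zeros_like(eig)
    coords = B @ W
    if dataset_ids is None:
        dataset_ids = [f"d{i}" for i in range(d)]
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(g)]
    return PcaResult(
        dataset_ids=list(dataset_ids),
        gene_ids=list(gene_ids),
        dataset_coords=coords,
        gene_loadings=W,
        eigenvalues=eig,
        variance_fraction=frac,
        left_vectors=U,
        source=source,
    )


def top_loading_genes(pca: PcaResult, pcs=(0, 1), k: int = 50) -> pd.DataFrame:
    """Genes ranked by mean absolute loading over *pcs*; top *k* returned.

    Ties break by gene id. Returns columns ``gene_id, mean_abs_loading``.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    pcs = list(pcs)
    if max(pcs) >= pca.gene_loadings.shape[1]:
        raise ConfigurationError("requested component beyond available PCs")
    score = np.mean(np.abs(pca.gene_loadings[:, pcs]), axis=1)
    df = pd.DataFrame({"gene_id": pca.gene_ids, "mean_abs_loading": score})
    df = df.sort_values(
        ["mean_abs_loading", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return df.head(k).reset_index(drop=True)


def prune_by_distance(
    genes: pd.DataFrame, positions: pd.DataFrame, min_sep: float = 0.1
) -> pd.DataFrame:
    """Drop the latter gene of any same-chromosome pair closer than *min_sep* cM.

    *genes* is a ranked list with a ``gene_id`` column; *positions* supplies
    ``gene_id, chrom, pos_cm`` (e.g. interval midpoints). Genes are scanned in
    genomic order; when a gene falls within *min_sep* of the previously
    retained gene on the same chromosome, the one with the larger coordinate
    is removed. The surviving subset is returned in the input ranking order.
    """
    pos = positions.set_index("gene_id")
    missing = [g for g in genes["gene_id"] if g not in pos.index
               or not np.isfinite(pos.loc[g, "pos_cm"])]
    if missing:
        raise ValidationError(f"genes missing cM coordinates: {missing[:5]}")
    sub = pos.loc[genes["gene_id"], ["chrom", "pos_cm"]].reset_index()
    sub = sub.sort_values(["chrom", "pos_cm"], kind="mergesort")
    kept: set[str] = set()
    last_chrom, last_cm = None, None
    for row in sub.itertuples(index=False):
        if row.chrom == last_chrom and row.pos_cm - last_cm < min_sep:
            continue
        kept.add(row.gene_id)
        last_chrom, last_cm = row.chrom, row.pos_cm
    return genes[genes["gene_id"].isin(kept)].reset_index(drop=True)


def correlate_loadings(pca_a: PcaResult, pca_b: PcaResult, pcs=(0, 1), k: int = 50):
    """Replication check: correlation of top-gene loadings across two analyses.

    Selects the *k* genes (shared universe) with the largest mean absolute
    loading over both analyses and the requested components, aligns each of
    B's component signs to A's by the sign of their inner product, then
    returns the Pearson r and two-sided t-distribution p-value over the
    concatenated per-component loading vectors.
    """
    if k < 3:
        raise ConfigurationError("k must be >= 3 for a correlation")
    pcs = list(pcs)
    shared = sorted(set(pca_a.gene_ids) & set(pca_b.gene_ids))
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared genes")
    ia = pd.Index(pca_a.gene_ids).get_indexer(shared)
    ib = pd.Index(pca_b.gene_ids).get_indexer(shared)
    A = pca_a.gene_loadings[ia][:, pcs]
    Bm = pca_b.gene_loadings[ib][:, pcs]
    # align component signs (PCs are defined up to sign)
    for j in range(len(pcs)):
        if np.dot(A[:, j], Bm[:, j]) < 0:
            Bm[:, j] = -Bm[:, j]
    score = (np.abs(A).mean(axis=1) + np.abs(Bm).mean(axis=1)) / 2
    order = np.argsort(-score, kind="mergesort")[: min(k, len(shared))]
    r, p = stats.pearsonr(A[order].ravel(), Bm[order].ravel())
    return float(r), float(p)


def filter_region(
    genes: pd.DataFrame, region: tuple[str, int, int] = HLA_REGION
) -> pd.DataFrame:
    """Remove genes overlapping a genomic region (default: extended HLA locus)."""
    chrom, start, end = region
    hit = (
        (genes["chrom"].astype(str) == str(chrom))
        & (genes["start_bp"] <= end)
        & (genes["end_bp"] >= start)
    )
    return genes[~hit].reset_index(drop=True)
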