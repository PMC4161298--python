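"""SNP-to-gene assignment by genetic (cM) or physical (bp) distance.

Each SNP is assigned to at most one gene: the gene it falls inside, or the
nearest gene within the window (0.01 cM genetic / 10 kb physical by default);
SNPs farther than the window from every gene are discarded. Distance to a
gene is zero inside the gene body and otherwise the distance to the nearer
boundary. Ties are broken deterministically: nearest distance, then smaller
gene start coordinate, then lexicographic gene id; a SNP inside two
overlapping gene bodies goes to the gene with the nearer midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

GENETIC_WINDOW_CM = 0.01
PHYSICAL_WINDOW_BP = 10_000

_CHUNK = 512  # SNPs per broadcasting block; bounds memory at _CHUNK * n_genes


@dataclass
class SnpGeneMap:
    """Result of :func:`map_snps_to_genes`.

    Attributes
    ----------
    assignment
        Per-SNP gene id aligned to the input SNP order; ``None`` (NaN) for
        discarded SNPs.
    gene_snps
        gene_id → integer row positions of its SNPs, in (chrom, pos) order
        because the input is coordinate-sorted.
    mode, window
        The distance mode ("genetic" or "physical") and window used.
    """

    assignment: pd.Series
    gene_snps: dict[str, np.ndarray] = field(default_factory=dict)
    mode: str = "genetic"
    window: float = GENETIC_WINDOW_CM

    def n_snps_per_gene(self) -> dict[str, int]:
        return {g: len(idx) for g, idx in self.gene_snps.items()}

    def to_frame(self, snps: pd.DataFrame) -> pd.DataFrame:
        """Audit table: snp_id and assigned gene_id ('.' when discarded)."""
        return pd.DataFrame(
            {"snp_id": snps["snp_id"].to_numpy(),
             "gene_id": self.assignment.fillna(".").to_numpy()}
        )


def _gene_coords(genes: pd.DataFrame, mode: str):
    if mode == "genetic":
        if "start_cm" not in genes.columns or genes["start_cm"].isna().any():
            raise ConfigurationError(
                "genetic mapping mode requires cM coordinates on genes "
                "(annotate with a GeneticMap first)"
            )
        return (genes["start_cm"].to_numpy(float), genes["end_cm"].to_numpy(float))
    if mode == "physical":
        return (genes["start_bp"].to_numpy(float), genes["end_bp"].to_numpy(float))
    raise ConfigurationError(f"unknown mapping mode {mode!r}")


def _snp_coords(snps: pd.DataFrame, mode: str) -> np.ndarray:
    if mode == "genetic":
        if "pos_cm" not in snps.columns or snps["pos_cm"].isna().any():
            raise ConfigurationError(
                "genetic mapping mode requires cM coordinates on SNPs"
            )
        return snps["pos_cm"].to_numpy(float)
    return snps["pos_bp"].to_numpy(float)


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    mode: str = "genetic",
    window: float | None = None,
) -> SnpGeneMap:
    """Assign every SNP to its nearest gene within *window*, or discard it.

    Parameters
    ----------
    snps
        Coordinate-sorted SNP table (``snp_id, chrom, pos_bp[, pos_cm]``).
    genes
        Gene intervals (``gene_id, chrom, start_bp, end_bp[, start_cm, end_cm]``).
    mode
        "genetic" (distances in cM) or "physical" (distances in bp).
    window
        Maximum SNP-to-gene distance; defaults to 0.01 cM or 10 kb per mode.
    """
    if window is None:
        window = GENETIC_WINDOW_CM if mode == "genetic" else PHYSICAL_WINDOW_BP
    if window <= 0:
        raise ConfigurationError("window must be positive")
    start, end = _gene_coords(genes, mode)
    pos = _snp_coords(snps, mode)
    mid = (start + end) / 2.0
    gene_ids = genes["gene_id"].to_numpy()
    gene_start_sort = genes["start_bp"].to_numpy(float) if mode == "physical" else start
    # tie-break key per gene: (start coordinate, gene_id)
    gene_rank = np.lexsort((gene_ids, gene_start_sort))
    tie_order = np.empty(len(gene_ids), dtype=int)
    tie_order[gene_rank] = np.arange(len(gene_ids))

    assigned = np.full(len(snps), -1, dtype=int)
    snp_chrom = snps["chrom"].to_numpy()
    gene_chrom = genes["chrom"].to_numpy()
    for chrom in pd.unique(snp_chrom):
        s_idx = np.flatnonzero(snp_chrom == chrom)
        g_idx = np.flatnonzero(gene_chrom == chrom)
        if g_idx.size == 0:
            continue
        gs, ge, gm, gt = start[g_idx], end[g_idx], mid[g_idx], tie_order[g_idx]
        for lo in range(0, s_idx.size, _CHUNK):
            block = s_idx[lo : lo + _CHUNK]
            p = pos[block][:, None]
            dist = np.maximum.reduce([gs[None, :] - p, p - ge[None, :],
                                      np.zeros((block.size, g_idx.size))])
            inside = dist == 0.0
            # among overlapping bodies prefer nearest midpoint; encode both
            # criteria into one sortable key per (snp, gene)
            mid_dist = np.abs(p - gm[None, :])
            key = np.where(inside, mid_dist, dist)
            key = np.where(dist <= window, key, np.inf)
            # genes inside the body always beat genes outside it
            primary = np.where(inside, 0, 1)
            best = _argmin_composite(primary, key, np.broadcast_to(gt, key.shape))
            valid = np.isfinite(key[np.arange(block.size), best])
            assigned[block[valid]] = g_idx[best[valid]]

    gene_col = pd.Series(
        [gene_ids[a] if a >= 0 else None for a in assigned], index=snps.index, dtype=object
    )
    gene_snps: dict[str, np.ndarray] = {}
    for gid in gene_ids:
        rows = np.flatnonzero(gene_col.to_numpy() == gid)
        if rows.size:
            gene_snps[gid] = rows
    return SnpGeneMap(assignment=gene_col, gene_snps=gene_snps, mode=mode, window=window)


def _argmin_composite(primary: np.ndarray, key: np.ndarray, tie: np.ndarray) -> np.ndarray:
    """Row-wise argmin under lexicographic (primary, key, tie) ordering."""
    n, m = key.shape
    best = np.zeros(n, dtype=int)
    cols = np.arange(m)
    for i in range(n):
        order = np.lexsort((tie[i], key[i], primary[i]))
        best[i] = cols[order[0]]
    return best
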