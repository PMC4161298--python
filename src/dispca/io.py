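"""Readers and writers for the external formats dispca consumes and emits.

Formats
-------
Summary statistics
    Whitespace/tab-delimited with a header (PLINK ``.assoc`` style). Default
    column names are ``SNP``, ``CHR``, ``BP``, ``P``; a *dialect* mapping can
    rename them. Coordinates are 1-based.
Gene annotation
    BED-like 4 columns without header: chrom, start, end, gene_id. BED is
    0-based half-open on disk; in memory intervals are 1-based closed
    (``start_bp = start + 1``, ``end_bp = end``).
Genetic map
    HapMap/Oxford style: position (bp), recombination rate (cM/Mb, ignored on
    read) and cumulative genetic position (cM), with a leading chromosome
    column so one file covers the genome.
Covariates
    Tab-delimited with header ``dataset_id``, ``array``, ``method``, ``n``.
Gene scores / score matrix / ranked export
    TSV; the ranked export is the two-column GSEA ``.rnk`` format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical summary-statistic columns, in order
SUMMARY_COLUMNS = ("snp_id", "chrom", "pos_bp", "p_value")

#: default file-column → canonical-column mapping (PLINK .assoc names)
DEFAULT_DIALECT: Mapping[str, str] = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos_bp",
    "P": "p_value",
}


def read_summary_stats(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read per-SNP association results.

    Parameters
    ----------
    path
        Whitespace/tab-delimited file with a header row.
    dialect
        Optional mapping from file column names to the canonical names
        ``snp_id``, ``chrom``, ``pos_bp``, ``p_value``. Defaults to the
        PLINK names ``SNP``/``CHR``/``BP``/``P``.

    Returns
    -------
    pandas.DataFrame
        Columns ``snp_id, chrom, pos_bp, p_value`` sorted by
        ``(chrom, pos_bp)``. Rows with missing or non-numeric p-values are
        dropped (a count is logged); p-values outside (0, 1] raise
        :class:`~dispca.exceptions.ValidationError`.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str})
    mapping = dict(DEFAULT_DIALECT if dialect is None else dialect)
    df = df.rename(columns=mapping)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df.loc[:, list(SUMMARY_COLUMNS)].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    n_bad = int(df["p_value"].isna().sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with missing/non-numeric p", path, n_bad)
        df = df.dropna(subset=["p_value"])
    out_of_range = (df["p_value"] <= 0) | (df["p_value"] > 1)
    if out_of_range.any():
        bad = df.loc[out_of_range, "snp_id"].iloc[0]
        raise ValidationError(
            f"{path}: p-value outside (0,1] for SNP {bad!r} "
            f"({int(out_of_range.sum())} offending rows)"
        )
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    if (df["pos_bp"] < 1).any():
        raise ValidationError(f"{path}: base-pair positions must be >= 1")
    df = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    return df


def write_summary_stats(snps: pd.DataFrame, path) -> None:
    """Write SNP association results in the default PLINK-style dialect."""
    inv = {v: k for k, v in DEFAULT_DIALECT.items()}
    out = snps.loc[:, list(SUMMARY_COLUMNS)].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def read_gene_intervals(path) -> pd.DataFrame:
    """Read a BED-like annotation into 1-based closed gene intervals.

    Returns a DataFrame with columns ``gene_id, chrom, start_bp, end_bp``.
    Duplicate gene ids raise :class:`ValidationError`.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str},
    )
    genes = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "chrom": df["chrom"],
            "start_bp": df["start"].astype(np.int64) + 1,
            "end_bp": df["end"].astype(np.int64),
        }
    )
    if (genes["start_bp"] > genes["end_bp"]).any():
        raise FormatError(f"{path}: interval with start > end")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    return genes


def write_gene_intervals(genes: pd.DataFrame, path) -> None:
    """Write 1-based closed gene intervals as 0-based half-open BED."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start_bp"].astype(np.int64) - 1,
            "end": genes["end_bp"].astype(np.int64),
            "gene_id": genes["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear map from physical (bp) to genetic (cM) position.

    Queries between map points are linearly interpolated; queries outside the
    mapped range clamp to the boundary cM value, so the map never extrapolates
    past the ends of a chromosome.
    """

    points: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (bp, cm) in self.points.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size == 0:
                raise FormatError(f"genetic map for {chrom}: malformed point arrays")
            if np.any(np.diff(bp) <= 0):
                raise FormatError(f"genetic map for {chrom}: bp not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"genetic map for {chrom}: cM column decreases")
            self.points[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.points)

    def interpolate(self, chrom: str, pos_bp) -> np.ndarray:
        """Map bp position(s) on *chrom* to cumulative cM (clamped at the ends)."""
        if chrom not in self.points:
            raise ValidationError(f"no genetic map for chromosome {chrom!r}")
        bp, cm = self.points[chrom]
        return np.interp(np.asarray(pos_bp, dtype=float), bp, cm)

    def annotate_snps(self, snps: pd.DataFrame) -> pd.DataFrame:
        """Return *snps* with a ``pos_cm`` column added."""
        out = snps.copy()
        out["pos_cm"] = np.nan
        for chrom, idx in out.groupby("chrom").groups.items():
            out.loc[idx, "pos_cm"] = self.interpolate(str(chrom), out.loc[idx, "pos_bp"])
        return out

    def annotate_genes(self, genes: pd.DataFrame) -> pd.DataFrame:
        """Return *genes* with ``start_cm``/``end_cm`` interpolated at the bp boundaries."""
        out = genes.copy()
        out["start_cm"] = np.nan
        out["end_cm"] = np.nan
        for chrom, idx in out.groupby("chrom").groups.items():
            out.loc[idx, "start_cm"] = self.interpolate(str(chrom), out.loc[idx, "start_bp"])
            out.loc[idx, "end_cm"] = self.interpolate(str(chrom), out.loc[idx, "end_bp"])
        return out


def read_genetic_map(path) -> GeneticMap:
    """Read a genome-wide genetic map (chrom, position, rate, cM).

    The rate column is ignored; only the cumulative cM column is used.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected 4 columns (chrom, position, rate, cM)")
    df.columns = ["chrom", "pos_bp", "rate", "cm"][: df.shape[1]]
    points = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp")
        points[str(chrom)] = (
            grp["pos_bp"].to_numpy(dtype=float),
            grp["cm"].to_numpy(dtype=float),
        )
    return GeneticMap(points)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    """Write a genetic map; the rate column is recomputed segment-wise in cM/Mb."""
    rows = []
    for chrom, (bp, cm) in gmap.points.items():
        rate = np.zeros_like(cm)
        if bp.size > 1:
            seg = np.diff(cm) / (np.diff(bp) / 1e6)
            rate[:-1] = seg
        for b, r, c in zip(bp, rate, cm):
            rows.append((chrom, int(b), r, c))
    out = pd.DataFrame(rows, columns=["chrom", "position", "rate_cM_Mb", "cM"])
    out.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read the per-dataset covariate table (dataset_id, array, method, n)."""
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "array": str, "method": str})
    required = ["dataset_id", "array", "method", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing covariate column(s) {missing}")
    df = df.loc[:, required]
    if df["dataset_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate dataset_id")
    if (df["n"] <= 0).any():
        raise ValidationError(f"{path}: sample sizes must be positive")
    return df


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index=False)


def write_gene_scores(table, path) -> None:
    """Write a :class:`~dispca.scores.GeneScoreTable` as TSV with metadata columns."""
    df = table.table.copy()
    df.insert(0, "dataset_id", table.dataset_id)
    df["method"] = table.method
    df["null_size"] = table.null_size
    df["seed"] = table.seed
    df.to_csv(path, sep="\t", index=False)


def read_gene_scores(path):
    """Read a gene-score TSV back into a :class:`~dispca.scores.GeneScoreTable`."""
    from .scores import GeneScoreTable  # deferred to avoid an import cycle

    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "gene_id": str})
    required = ["dataset_id", "gene_id", "n_snps", "raw_stat", "empirical_p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing gene-score column(s) {missing}")
    meta = df.iloc[0]
    table = df.loc[:, ["gene_id", "n_snps", "raw_stat", "empirical_p"]].reset_index(drop=True)
    return GeneScoreTable(
        dataset_id=str(meta["dataset_id"]),
        table=table,
        method=str(meta.get("method", "min_p")),
        null_size=int(meta.get("null_size", 0)),
        seed=int(meta["seed"]) if "seed" in df.columns and pd.notna(meta.get("seed")) else None,
    )


def write_score_matrix(matrix, path, metadata_path=None) -> None:
    """Persist a :class:`~dispca.pca.ScoreMatrix` as TSV plus a JSON sidecar.

    The TSV has datasets as rows (first column ``dataset_id``) and genes as
    columns. The sidecar holds the covariate table and any metadata.
    """
    df = pd.DataFrame(matrix.Z, columns=matrix.gene_ids)
    df.insert(0, "dataset_id", matrix.dataset_ids)
    df.to_csv(path, sep="\t", index=False)
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".meta.json")
    meta = {
        "covariates": matrix.covariates.to_dict(orient="records")
        if matrix.covariates is not None
        else None,
        "metadata": matrix.metadata,
    }
    Path(metadata_path).write_text(json.dumps(meta, indent=1))


def read_score_matrix(path, metadata_path=None):
    """Read a persisted score matrix (see :func:`write_score_matrix`)."""
    from .pca import ScoreMatrix  # deferred to avoid an import cycle

    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str})
    dataset_ids = df["dataset_id"].tolist()
    gene_ids = [c for c in df.columns if c != "dataset_id"]
    Z = df.loc[:, gene_ids].to_numpy(dtype=float)
    covariates = None
    metadata = {}
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".meta.json")
    metadata_path = Path(metadata_path)
    if metadata_path.exists():
        meta = json.loads(metadata_path.read_text())
        if meta.get("covariates") is not None:
            covariates = pd.DataFrame(meta["covariates"])
        metadata = meta.get("metadata") or {}
    return ScoreMatrix(Z=Z, dataset_ids=dataset_ids, gene_ids=gene_ids,
                       covariates=covariates, metadata=metadata)


def write_rnk(gene_ids: Sequence[str], scores, path) -> None:
    """Write a GSEA pre-ranked ``.rnk`` file (gene, score; descending score).

    Duplicate gene ids raise :class:`ValidationError`; the file has no header.
    """
    gene_ids = list(gene_ids)
    scores = np.asarray(scores, dtype=float)
    if len(gene_ids) != scores.size:
        raise ValidationError("one score per gene required")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("duplicate gene ids in ranked export")
    order = np.argsort(-scores, kind="mergesort")
    with open(path, "w") as fh:
        for i in order:
            fh.write(f"{gene_ids[i]}\t{scores[i]}\n")


def read_rnk(path) -> pd.DataFrame:
    """Read a ``.rnk`` file back (columns ``gene_id``, ``score``)."""
    try:
        return pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["gene_id", "score"])
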