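"""Synthetic data generators: the gene-level pleiotropy simulation and a
SNP-level GWAS summary-statistic generator.

The gene-level design draws a diseases x genes p-value matrix directly.
Two disease classes of five diseases each (A1..A5, B1..B5) share 10,000
genes. Three disjoint gene sets define the signal structure:

* background genes: p ~ U(0,1) in every disease (no pleiotropy);
* a "class-A" set: p ~ U(0, 0.05) in A1..A5, U(0,1) in class B —
  pleiotropy within class A;
* a "cross-class" set: p ~ U(0, 0.05) in A1, A2, B1, B2, U(0,1)
  elsewhere — pleiotropy spanning the two classes.

Both signal sets default to 40 genes. Running disPCA on such a matrix
separates the cross-class quartet on one component and the two classes on
the other, which hierarchical clustering on those two components recovers
as four groups: {A1,A2}, {B1,B2}, {A3..A5}, {B3..B5}.

The SNP-level generator emits complete pipeline inputs (summary statistics,
BED annotation, genetic map, covariates, truth table) with planted
associated genes whose SNP p-values are drawn U(0, p_max). It models no
linkage disequilibrium between SNPs and no effect sizes: signals live
purely in the p-value distributions, matching the gene-level design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .cluster import grouping_correct, hierarchical_cluster, pc_distances
from .exceptions import ValidationError
from .pca import run_pca

SIG_MAX = 0.05  # upper bound of the associated-gene p-value distribution


@dataclass
class SimulationDesign:
    """Parameters of the gene-level pleiotropy simulation."""

    n_per_class: int = 5
    n_genes: int = 10_000
    set2_size: int = 40     # class-A pleiotropy set
    set3_size: int = 40     # cross-class quartet set
    sig_max: float = SIG_MAX
    seed: int | None = 0

    @property
    def disease_ids(self) -> list[str]:
        return [f"A{i+1}" for i in range(self.n_per_class)] + [
            f"B{i+1}" for i in range(self.n_per_class)
        ]


def simulate_pleiotropy_matrix(design: SimulationDesign | None = None,
                               rng: np.random.Generator | None = None):
    """Draw the diseases x genes p-value matrix of the pleiotropy design.

    Returns ``(P, truth)`` where ``P`` is a DataFrame (rows = diseases,
    columns = gene ids) and ``truth`` maps ``"class_a_set"`` and
    ``"cross_class_set"`` to the signal gene ids (the last columns).
    """
    design = design or SimulationDesign()
    if design.set2_size + design.set3_size > design.n_genes:
        raise ValidationError("signal sets exceed the number of genes")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n_d = 2 * design.n_per_class
    g = design.n_genes
    P = rng.uniform(0.0, 1.0, size=(n_d, g))
    # signal sets occupy the trailing columns: class-A set first, then the
    # cross-class set, mirroring how the loadings are displayed sequentially
    a_lo = g - design.set2_size - design.set3_size
    a_hi = g - design.set3_size
    class_a = np.arange(design.n_per_class)
    quartet = np.array([0, 1, design.n_per_class, design.n_per_class + 1])
    if design.set2_size:
        P[np.ix_(class_a, np.arange(a_lo, a_hi))] = rng.uniform(
            0.0, design.sig_max, size=(class_a.size, design.set2_size)
        )
    if design.set3_size:
        P[np.ix_(quartet, np.arange(a_hi, g))] = rng.uniform(
            0.0, design.sig_max, size=(quartet.size, design.set3_size)
        )
    np.clip(P, np.nextafter(0, 1), 1.0, out=P)
    gene_ids = [f"G{j:05d}" for j in range(g)]
    frame = pd.DataFrame(P, index=design.disease_ids, columns=gene_ids)
    truth = {
        "class_a_set": gene_ids[a_lo:a_hi],
        "cross_class_set": gene_ids[a_hi:],
    }
    return frame, truth


def expected_groups(design: SimulationDesign | None = None) -> list[frozenset[str]]:
    """The 4-way partition a successful analysis must recover.

    The cross-class quartet splits by class on one PC while the other PC
    isolates it, so the joint 2-PC structure is four groups: the quartet's
    class-A and class-B halves and the two class backgrounds.
    """
    design = design or SimulationDesign()
    ids = design.disease_ids
    m = design.n_per_class
    return [
        frozenset(ids[:2]),               # A1, A2
        frozenset(ids[m : m + 2]),        # B1, B2
        frozenset(ids[2:m]),              # A3..A5
        frozenset(ids[m + 2 :]),          # B3..B5
    ]


def dispca_cluster(P: pd.DataFrame, n_pcs: int = 2, linkage: str = "complete"):
    """Run disPCA (no covariates) on a p-value matrix and cluster the datasets.

    Returns ``(pca, tree)``: the centered unscaled PCA of ``-log10 P`` and
    the complete-linkage tree on Euclidean distances over the first *n_pcs*
    dataset coordinates.
    """
    Z = -np.log10(P.to_numpy(dtype=float))
    pca = run_pca(Z, dataset_ids=list(P.index), gene_ids=list(P.columns))
    D = pc_distances(pca.dataset_coords, n_pcs)
    tree = hierarchical_cluster(D, labels=list(P.index), linkage=linkage)
    return pca, tree


def recovery_rate(set_size: int, n_reps: int = 50, seed: int = 0,
                  design: SimulationDesign | None = None) -> float:
    """Fraction of replicates whose dendrogram recovers the planted groups.

    Each replicate simulates the design with both signal sets at *set_size*
    genes, runs disPCA, clusters on the first two PCs and checks the 4-way
    cut against :func:`expected_groups`.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    base = design or SimulationDesign()
    groups = expected_groups(base)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        d = SimulationDesign(
            n_per_class=base.n_per_class, n_genes=base.n_genes,
            set2_size=set_size, set3_size=set_size, sig_max=base.sig_max,
        )
        P, _ = simulate_pleiotropy_matrix(d, rng=rng)
        _, tree = dispca_cluster(P)
        hits += grouping_correct(tree, groups)
    return hits / n_reps


@dataclass
class SnpLevelSpec:
    """Parameters of the SNP-level summary-statistic generator."""

    n_datasets: int = 4
    n_chromosomes: int = 2
    snps_per_chromosome: int = 500
    snp_spacing_bp: int = 5_000
    gene_length_bp: int = 20_000
    gene_gap_bp: int = 30_000
    cm_per_mb: float = 1.0
    n_planted_per_dataset: int = 3
    shared_planted: int = 0   # planted genes common to all datasets
    sig_max: float = SIG_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_per_dataset < self.shared_planted:
            raise ValidationError("shared_planted exceeds planted count")


@dataclass
class SyntheticStudy:
    """In-memory bundle of generated pipeline inputs."""

    snps: dict[str, pd.DataFrame]          # dataset_id -> summary stats
    genes: pd.DataFrame
    genetic_map: gio.GeneticMap
    covariates: pd.DataFrame
    truth: pd.DataFrame                    # dataset_id, gene_id (planted)
    spec: SnpLevelSpec = field(repr=False, default=None)

    def write(self, outdir) -> dict[str, Path]:
        """Write all inputs in the standard on-disk formats; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for ds, df in self.snps.items():
            p = outdir / f"{ds}.assoc"
            gio.write_summary_stats(df, p)
            paths[ds] = p
        paths["genes"] = outdir / "genes.bed"
        gio.write_gene_intervals(self.genes, paths["genes"])
        paths["map"] = outdir / "genetic_map.txt"
        gio.write_genetic_map(self.genetic_map, paths["map"])
        paths["covariates"] = outdir / "covariates.tsv"
        gio.write_covariates(self.covariates, paths["covariates"])
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_snp_level(spec: SnpLevelSpec | None = None) -> SyntheticStudy:
    """Generate SNP-level GWAS inputs with planted associated genes.

    Chromosomes carry evenly spaced SNPs and tiled gene intervals under a
    linear genetic map. Per dataset, SNPs mapped inside planted genes draw
    p ~ U(0, sig_max); all other SNPs draw U(0,1). Covariates (array,
    method, sample size) are assigned cyclically so the confounder design
    is exercised end to end.
    """
    spec = spec or SnpLevelSpec()
    rng = np.random.default_rng(spec.seed)

    genes_rows = []
    chrom_ids = [str(c + 1) for c in range(spec.n_chromosomes)]
    chrom_len = spec.snps_per_chromosome * spec.snp_spacing_bp + spec.snp_spacing_bp
    for c in chrom_ids:
        start = 10_000
        gi = 0
        while start + spec.gene_length_bp < chrom_len:
            genes_rows.append(
                (f"GENE{c}_{gi:03d}", c, start, start + spec.gene_length_bp)
            )
            start += spec.gene_length_bp + spec.gene_gap_bp
            gi += 1
    genes = pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])

    gmap = gio.GeneticMap(
        {
            c: (
                np.array([1.0, float(chrom_len)]),
                np.array([0.0, chrom_len / 1e6 * spec.cm_per_mb]),
            )
            for c in chrom_ids
        }
    )

    pos = np.arange(1, spec.snps_per_chromosome + 1) * spec.snp_spacing_bp
    snp_rows = []
    for c in chrom_ids:
        for i, bp in enumerate(pos):
            snp_rows.append((f"rs{c}_{i:05d}", c, int(bp)))
    base = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos_bp"])

    # SNPs inside each gene body (planted signal is placed on these)
    gene_snp_rows: dict[str, np.ndarray] = {}
    for row in genes.itertuples(index=False):
        mask = (
            (base["chrom"] == row.chrom)
            & (base["pos_bp"] >= row.start_bp)
            & (base["pos_bp"] <= row.end_bp)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size:
            gene_snp_rows[row.gene_id] = idx
    eligible = sorted(gene_snp_rows)

    shared = list(
        rng.choice(eligible, size=min(spec.shared_planted, len(eligible)), replace=False)
    )
    datasets = {}
    truth_rows = []
    arrays = ["chipA", "chipB"]
    methods = ["logistic", "trend"]
    cov_rows = []
    for d in range(spec.n_datasets):
        ds = f"DS{d+1}"
        extra_pool = [g for g in eligible if g not in shared]
        n_extra = spec.n_planted_per_dataset - len(shared)
        planted = shared + list(rng.choice(extra_pool, size=n_extra, replace=False))
        p = rng.uniform(0.0, 1.0, size=len(base))
        for g in planted:
            idx = gene_snp_rows[g]
            p[idx] = rng.uniform(0.0, spec.sig_max, size=idx.size)
            truth_rows.append((ds, g))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        df = base.copy()
        df["p_value"] = p
        datasets[ds] = df
        cov_rows.append(
            (ds, arrays[d % 2], methods[(d // 2) % 2], int(rng.integers(1000, 10000)))
        )
    covariates = pd.DataFrame(cov_rows, columns=["dataset_id", "array", "method", "n"])
    truth = pd.DataFrame(truth_rows, columns=["dataset_id", "gene_id"])
    return SyntheticStudy(
        snps=datasets, genes=genes, genetic_map=gmap,
        covariates=covariates, truth=truth, spec=spec,
    )
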