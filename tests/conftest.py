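import numpy as np
import pandas as pd
import pytest

from dispca.io import GeneticMap
from dispca.simulate import SnpLevelSpec, simulate_snp_level


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_map():
    """Two chromosomes with simple piecewise-linear bp→cM maps."""
    return GeneticMap(
        {
            "1": (np.array([1_000.0, 2_000.0, 5_000.0]), np.array([0.0, 1.0, 1.5])),
            "2": (np.array([1_000.0, 10_000.0]), np.array([0.0, 0.9])),
        }
    )


@pytest.fixture
def small_study():
    """Small synthetic SNP-level study exercised by several suites."""
    return simulate_snp_level(
        SnpLevelSpec(
            n_datasets=3, n_chromosomes=2, snps_per_chromosome=300,
            n_planted_per_dataset=3, seed=11,
        )
    )


def random_snps(rng, n_snps, chroms=("1", "2"), span_cm=2.0):
    """Random coordinate-sorted SNP table with cM positions and U(0,1) p."""
    rows = []
    for c in chroms:
        k = n_snps // len(chroms)
        pos = np.sort(rng.choice(np.arange(1, 500_000), size=k, replace=False))
        cm = np.sort(rng.uniform(0, span_cm, size=k))
        for b, g in zip(pos, cm):
            rows.append((f"rs{c}_{b}", c, int(b), g))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "pos_cm"])
    df["p_value"] = rng.uniform(size=len(df)).clip(1e-12, 1.0)
    return df.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)


def random_genes(rng, n_genes, chroms=("1", "2"), span_cm=2.0):
    """Random gene intervals with cM boundaries (non-overlapping per chrom)."""
    rows = []
    for c in chroms:
        k = n_genes // len(chroms)
        edges_bp = np.sort(rng.choice(np.arange(1, 500_000), size=2 * k, replace=False))
        edges_cm = np.sort(rng.uniform(0, span_cm, size=2 * k))
        for i in range(k):
            rows.append(
                (f"G{c}_{i}", c, int(edges_bp[2 * i]), int(edges_bp[2 * i + 1]),
                 edges_cm[2 * i], edges_cm[2 * i + 1])
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start_bp", "end_bp", "start_cm", "end_cm"]
    )
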