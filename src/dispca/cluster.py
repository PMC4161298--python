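"""Hierarchical clustering of datasets in PC space and the cross-disease
Fisher's-method test.

Datasets are clustered agglomeratively on the Euclidean distance between
their coordinates on the first PCs (complete linkage by default). The merge
table uses the scipy linkage layout so trees interoperate with scipy's
dendrogram utilities, but the agglomeration itself is done here so that
distance ties resolve deterministically (smallest cluster-id pair).

The cross-disease test takes the k genes nominally significant in a source
dataset (empirical p < 0.01), optionally prunes same-chromosome genes closer
than 0.1 cM, and combines their p-values in a target dataset with Fisher's
method: T = -2 * sum(ln p_i) referred to chi-square with 2k degrees of
freedom, testing a uniform (non-enriched) target distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .scores import GeneScoreTable

LINKAGES = ("single", "complete", "average")


@dataclass
class ClusterTree:
    """Agglomerative merge tree over datasets.

    ``merges`` follows the scipy linkage convention: row t merges clusters
    ``merges[t, 0]`` and ``merges[t, 1]`` (leaves are 0..n-1, the cluster
    formed at step t gets id n+t) at height ``merges[t, 2]`` with
    ``merges[t, 3]`` leaves in the result.
    """

    labels: list[str]
    merges: np.ndarray
    linkage: str = "complete"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> list[frozenset[str]]:
        """Partition the leaves into *k* clusters by undoing the last k-1 merges."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ConfigurationError(f"cannot cut a {n}-leaf tree into {k} clusters")
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for t in range(n - k):
            a, b = int(self.merges[t, 0]), int(self.merges[t, 1])
            members[n + t] = members.pop(a) | members.pop(b)
        return [frozenset(self.labels[i] for i in grp) for grp in members.values()]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for t in range(n - 1):
            a, b, h = int(self.merges[t, 0]), int(self.merges[t, 1]), self.merges[t, 2]
            la = h - height[a]
            lb = h - height[b]
            node[n + t] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + t] = h
        return node[2 * n - 2] + ";"

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )


@dataclass
class CrossTestResult:
    """Fisher's-method test of one disease's significant genes in another."""

    source: str
    target: str
    k: int
    statistic: float | None
    dof: int
    p_value: float | None
    pruned: bool = False

    @property
    def testable(self) -> bool:
        return self.k > 0


def pc_distances(coords: np.ndarray, n_pcs: int = 2) -> np.ndarray:
    """Pairwise Euclidean distances over the first *n_pcs* coordinate columns."""
    coords = np.asarray(coords, dtype=float)
    if n_pcs > coords.shape[1]:
        raise ConfigurationError(
            f"requested {n_pcs} PCs but only {coords.shape[1]} available"
        )
    X = coords[:, :n_pcs]
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def hierarchical_cluster(
    dist: np.ndarray, labels: list[str] | None = None, linkage: str = "complete"
) -> ClusterTree:
    """Naive O(n^3) agglomerative clustering with deterministic tie-breaks.

    *dist* is a symmetric zero-diagonal distance matrix. At each step the
    pair of active clusters at minimal linkage distance merges; exact ties
    resolve to the pair with the smallest (id_a, id_b). Inter-cluster
    distances follow Lance-Williams updates for single/complete/average.
    """
    if linkage not in LINKAGES:
        raise ConfigurationError(f"linkage must be one of {LINKAGES}")
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be square, symmetric, zero-diagonal")
    if labels is None:
        labels = [f"d{i}" for i in range(n)]
    if len(labels) != n:
        raise ValidationError("label count does not match matrix size")

    active: dict[int, dict] = {
        i: {"size": 1, "dist": {}} for i in range(n)
    }
    for i in range(n):
        for j in range(i + 1, n):
            active[i]["dist"][j] = D[i, j]
            active[j]["dist"][i] = D[i, j]

    merges = np.zeros((n - 1, 4))
    next_id = n
    for t in range(n - 1):
        best = None
        for a in sorted(active):
            for b, dab in sorted(active[a]["dist"].items()):
                if b <= a:
                    continue
                if best is None or dab < best[0] or (dab == best[0] and (a, b) < best[1:]):
                    best = (dab, a, b)
        h, a, b = best
        sa, sb = active[a]["size"], active[b]["size"]
        merges[t] = (a, b, h, sa + sb)
        new_dist = {}
        for c in active:
            if c in (a, b):
                continue
            dca = active[c]["dist"][a]
            dcb = active[c]["dist"][b]
            if linkage == "single":
                d_new = min(dca, dcb)
            elif linkage == "complete":
                d_new = max(dca, dcb)
            else:  # average (UPGMA)
                d_new = (sa * dca + sb * dcb) / (sa + sb)
            new_dist[c] = d_new
            del active[c]["dist"][a]
            del active[c]["dist"][b]
            active[c]["dist"][next_id] = d_new
        del active[a], active[b]
        active[next_id] = {"size": sa + sb, "dist": new_dist}
        next_id += 1
    return ClusterTree(labels=list(labels), merges=merges, linkage=linkage)


def grouping_correct(tree: ClusterTree, expected_groups) -> bool:
    """True iff cutting the tree into len(expected_groups) clusters reproduces them."""
    expected = [frozenset(g) for g in expected_groups]
    leaves = set(tree.labels)
    flat = [x for g in expected for x in g]
    if len(flat) != len(set(flat)) or set(flat) != leaves:
        raise ValidationError("expected_groups must partition the leaf set")
    return set(tree.cut(len(expected))) == set(expected)


def fisher_combine(p_values: np.ndarray):
    """Fisher's method: T = -2*sum(ln p), p from chi-square with 2k dof."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    T = float(-2.0 * np.sum(np.log(p)))
    dof = 2 * p.size
    return T, dof, float(stats.chi2.sf(T, dof))


def fisher_nonrandom(
    source: GeneScoreTable,
    target: GeneScoreTable,
    alpha_select: float = 0.01,
    prune_cm: float | None = None,
    gene_positions: pd.DataFrame | None = None,
) -> CrossTestResult:
    """Test whether the source's significant genes are enriched in the target.

    Genes with source empirical p strictly below *alpha_select* (and present
    in the target) are selected; with *prune_cm* set, same-chromosome genes
    within that genetic distance are thinned (latter of each pair removed,
    requires *gene_positions* with ``gene_id, chrom, pos_cm``). With k = 0
    the result is flagged untestable (no statistic or p-value emitted).
    """
    if not 0 < alpha_select < 1:
        raise ConfigurationError("alpha_select must lie in (0, 1)")
    src_p = source.p_series()
    tgt_p = target.p_series()
    selected = src_p.index[(src_p < alpha_select) & src_p.index.isin(tgt_p.index)]
    pruned = False
    if prune_cm is not None and len(selected):
        if gene_positions is None:
            raise ConfigurationError("prune_cm requires gene_positions")
        from .pca import prune_by_distance

        ranked = pd.DataFrame({"gene_id": list(selected)})
        selected = prune_by_distance(ranked, gene_positions, prune_cm)["gene_id"]
        pruned = True
    k = len(selected)
    if k == 0:
        return CrossTestResult(source.dataset_id, target.dataset_id, 0, None, 0,
                               None, pruned)
    T, dof, p = fisher_combine(tgt_p.loc[selected].to_numpy())
    return CrossTestResult(source.dataset_id, target.dataset_id, k, T, dof, p, pruned)


def fisher_matrix(
    tables,
    alpha_select: float = 0.01,
    prune_cm: float | None = None,
    gene_positions: pd.DataFrame | None = None,
) -> dict[tuple[str, str], CrossTestResult]:
    """All ordered source→target cross tests between >= 2 score tables."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValidationError("need at least two gene-score tables")
    out = {}
    for src in tables:
        for tgt in tables:
            if src.dataset_id == tgt.dataset_id:
                continue
            out[(src.dataset_id, tgt.dataset_id)] = fisher_nonrandom(
                src, tgt, alpha_select, prune_cm, gene_positions
            )
    return out


def fisher_neglog10_frame(results: dict[tuple[str, str], CrossTestResult]) -> pd.DataFrame:
    """-log10 p matrix (source rows, target columns); NaN where untestable."""
    sources = sorted({s for s, _ in results})
    targets = sorted({t for _, t in results})
    M = pd.DataFrame(np.nan, index=sources, columns=targets)
    for (s, t), res in results.items():
        if res.testable:
            M.loc[s, t] = -np.log10(res.p_value)
    return M
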