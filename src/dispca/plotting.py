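"""Minimal plot helpers: PC scatter and dendrogram. Requires matplotlib."""

from __future__ import annotations

import numpy as np


def pc_scatter(pca, pcs=(0, 1), ax=None, **scatter_kw):
    """Scatter datasets on two PCs, labelled by dataset id."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    i, j = pcs
    x = pca.dataset_coords[:, i]
    y = pca.dataset_coords[:, j]
    ax.scatter(x, y, **scatter_kw)
    for xi, yi, lab in zip(x, y, pca.dataset_ids):
        ax.annotate(lab, (xi, yi), fontsize=8)
    ax.set_xlabel(f"PC{i + 1} ({pca.variance_fraction[i]:.1%})")
    ax.set_ylabel(f"PC{j + 1} ({pca.variance_fraction[j]:.1%})")
    return ax


def dendrogram(tree, ax=None, **kw):
    """Draw a ClusterTree via scipy's dendrogram machinery."""
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    if ax is None:
        _, ax = plt.subplots()
    Z = np.asarray(tree.merges, dtype=float)
    hierarchy.dendrogram(Z, labels=tree.labels, ax=ax, **kw)
    ax.set_ylabel("Euclidean distance in PC space")
    return ax
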