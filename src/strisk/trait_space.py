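"""Comparing traits by their spatiotemporal enrichment profiles.

Each gene set's vector of per-sample (Z-scored) enrichment values is a
point in sample space; hierarchical clustering and a 2-D t-SNE embedding
summarize which traits share spatiotemporal expression dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)

__all__ = ["ClusterTree", "TraitEmbedding", "cluster_sets", "embed_sets"]


@dataclass
class ClusterTree:
    """Agglomerative clustering of gene sets over their profile vectors."""

    set_names: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    labels: pd.Series  # flat cluster labels at the requested cut
    linkage: str
    metric: str

    def to_newick(self) -> str:
        """Dendrogram in newick format (branch lengths = merge heights)."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.set_names[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def cluster_sets(
    z_matrix: pd.DataFrame,
    linkage: str = "complete",
    metric: str = "euclidean",
    n_clusters: int = 2,
) -> ClusterTree:
    """Hierarchically cluster gene sets by their profile rows.

    Missing cells are imputed to 0 (null enrichment) before distance
    computation; this is logged. Flat labels are taken at ``n_clusters``.
    The defaults (complete linkage on Euclidean distances) match the
    conventions of the standard heatmap-clustering tools.
    """
    if z_matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    X = z_matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("imputing %d missing profile cells to 0 before clustering", n_missing)
        X = np.nan_to_num(X, nan=0.0)
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    names = list(z_matrix.index)
    return ClusterTree(
        set_names=names,
        linkage_matrix=Z,
        leaf_order=[names[i] for i in order],
        labels=pd.Series(labels, index=names, name="cluster"),
        linkage=linkage,
        metric=metric,
    )


@dataclass
class TraitEmbedding:
    """2-D stochastic-neighbor embedding of gene-set enrichment profiles."""

    coords: pd.DataFrame  # one row per set, columns tsne1/tsne2
    perplexity: float
    seed: int
    n_iter: int
    kl_divergence: float


def embed_sets(
    r_matrix: pd.DataFrame,
    perplexity: float = 5.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> TraitEmbedding:
    """t-SNE embedding of gene sets from their per-sample enrichment rows.

    PCA initialization and a fixed seed keep the small-n embedding
    reproducible; the achieved KL divergence is reported. Requires
    ``perplexity < n_sets`` and at least 4 sets.
    """
    n_sets = r_matrix.shape[0]
    if n_sets < 4:
        raise ValueError(f"need at least 4 sets to embed, got {n_sets}")
    if perplexity >= n_sets:
        raise ValueError(f"perplexity {perplexity} must be < number of sets {n_sets}")
    X = np.nan_to_num(r_matrix.to_numpy(dtype=float), nan=0.0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        init="pca",
        random_state=seed,
    )
    Y = tsne.fit_transform(X)
    if not np.isfinite(Y).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    coords = pd.DataFrame(Y, index=r_matrix.index, columns=["tsne1", "tsne2"])
    return TraitEmbedding(
        coords=coords,
        perplexity=perplexity,
        seed=seed,
        n_iter=n_iter,
        kl_divergence=float(tsne.kl_divergence_),
    )
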