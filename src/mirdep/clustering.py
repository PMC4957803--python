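"""Hierarchical clustering of samples on a selected gene panel.

Defaults follow expression-heatmap convention: per-gene z-scoring, correlation
distance (1 - Pearson R between sample profiles) and average linkage.  The
typical query: after restricting to a panel of miRNA-dependent genes and
candidate targets, do the knockout activated samples cluster with the resting
samples rather than with the wild-type activated ones?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import ExpressionMatrix, GeneSet


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4): ids merged, height, cluster size
    leaves: list[str]  # sample ids, in input order (node ids 0..n-1)
    metric: str
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram display order."""
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        """Cut into k flat clusters; returns cluster id per leaf."""
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > self.n_leaves:
            raise ValueError(f"k={k} exceeds {self.n_leaves} leaves")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaves, name="cluster")

    def to_newick(self) -> str:
        """Newick serialisation with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def _render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            left = _render(node.left, node.dist)
            right = _render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({_render(tree.left, tree.dist)},{_render(tree.right, tree.dist)});"

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.linkage, columns=["node_a", "node_b", "height", "size"]
        ).to_csv(path, sep="\t", index=False)


def cluster_samples(
    matrix: ExpressionMatrix,
    panel: GeneSet | list[str] | None = None,
    metric: str = "correlation",
    method: str = "average",
    standardize: bool = True,
) -> Dendrogram:
    """Cluster samples on the expression of a gene panel.

    Parameters
    ----------
    panel
        Probes/symbols to restrict to (matched case-insensitively); None uses
        all probes.  At least 2 genes and 3 samples are required.
    standardize
        Z-score each gene across samples before computing distances (heatmap
        convention; irrelevant for correlation distance up to degeneracies).
    """
    values = matrix.values
    if panel is not None:
        members = panel.members if isinstance(panel, GeneSet) else list(panel)
        probes = GeneSet(name="panel", members=[str(m) for m in members]).match(values.index)
        if matrix.gene_symbols is not None:
            wanted = {str(m).lower() for m in members}
            probes += [
                p
                for p, sym in matrix.gene_symbols.items()
                if str(sym).lower() in wanted and p not in probes
            ]
        if not probes:
            raise KeyError("no panel gene found in the expression matrix")
        values = values.loc[probes]
    if values.shape[0] < 2:
        raise ValueError(f"need >=2 genes to cluster samples, got {values.shape[0]}")
    if values.shape[1] < 3:
        raise ValueError(f"need >=3 samples, got {values.shape[1]}")

    data = values.to_numpy(dtype=float)
    if standardize:
        sd = data.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=1, keepdims=True)) / sd

    profiles = data.T  # samples x genes
    if metric == "correlation":
        flat = profiles.std(axis=1) == 0
        if flat.any():
            bad = values.columns[np.flatnonzero(flat)[0]]
            raise ValueError(f"sample {bad!r} has a zero-variance profile on this panel")
    dists = pdist(profiles, metric=metric)
    linkage = hierarchy.linkage(dists, method=method)
    return Dendrogram(
        linkage=linkage, leaves=list(values.columns), metric=metric, method=method
    )


def nearest_major_cluster(
    dendrogram: Dendrogram, query_samples: list[str], k: int = 2
) -> pd.DataFrame:
    """Cut into k clusters and report each query's cluster and co-members."""
    assignment = dendrogram.cut(k)
    rows = []
    for q in query_samples:
        if q not in assignment.index:
            raise KeyError(f"query sample {q!r} is not a leaf of the dendrogram")
        cid = int(assignment.loc[q])
        co = [s for s in assignment.index[assignment == cid] if s != q]
        rows.append({"sample": q, "cluster": cid, "co_members": ",".join(co)})
    return pd.DataFrame(rows).set_index("sample")
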