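"""Tree-landscape exploration with the Kendall–Colijn metric.

Each rooted tree on n tips is embedded as a vector of length C(n,2) + n:
for every tip pair, the root-to-MRCA depth blended between edge counts
(topology) and path lengths by a parameter lambda in [0, 1]; plus one
pendant entry per tip (1 blended with the pendant branch length).  The KC
distance is the Euclidean distance between vectors; lambda = 0 is purely
topological and is zero exactly when two rooted topologies agree.

The landscape procedure mirrors treespace's ``findGroves``/``med.trees``:
classical metric MDS (principal coordinates) of the KC distance matrix,
Ward-linkage hierarchical clustering on the retained axes cut into a fixed
number of groups, and per-cluster summary trees (the member tree
minimizing the summed KC distance to its cluster, plus a majority-rule
consensus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .trees import TreeValidationError, consensus_tree, tip_labels

__all__ = [
    "kc_vector",
    "kc_distance_matrix",
    "embed_and_cluster",
    "cluster_summary_trees",
    "find_groves",
    "LandscapeResult",
]


def kc_vector(tree: dendropy.Tree, lam: float = 0.0) -> np.ndarray:
    """Kendall–Colijn vector of a rooted tree, tips in sorted label order."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if len(tree.seed_node.child_nodes()) != 2:
        raise TreeValidationError("Kendall–Colijn vectors require rooted trees")
    labels = sorted(tip_labels(tree))

    # root-to-node edge counts and path lengths
    edge_count = {tree.seed_node: 0}
    path_len = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge_count[node] = edge_count[node.parent_node] + 1
        path_len[node] = path_len[node.parent_node] + (node.edge.length or 0.0)

    leaf_of = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    # MRCA via leafset ancestors: walk up from each leaf recording ancestry order
    anc = {}
    for label, leaf in leaf_of.items():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[label] = chain

    entries = []
    for la, lb in combinations(labels, 2):
        chain_b = set(anc[lb])
        mrca = next(n for n in anc[la] if n in chain_b)
        entries.append((1.0 - lam) * edge_count[mrca] + lam * path_len[mrca])
    for label in labels:
        pend = leaf_of[label].edge.length or 0.0
        entries.append((1.0 - lam) * 1.0 + lam * pend)
    return np.asarray(entries)


def kc_distance_matrix(trees: list[dendropy.Tree], lam: float = 0.0) -> np.ndarray:
    """Pairwise Euclidean distances between KC vectors."""
    ref = tip_labels(trees[0])
    for t in trees[1:]:
        if tip_labels(t) != ref:
            raise TreeValidationError("KC distances require identical tip sets")
    vectors = np.vstack([kc_vector(t, lam) for t in trees])
    diff = vectors[:, None, :] - vectors[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


@dataclass
class LandscapeResult:
    coordinates: np.ndarray            # trees x naxes
    labels: np.ndarray                 # 1-based cluster ids
    eigenvalues: np.ndarray            # all PCoA eigenvalues, descending
    median_trees: dict[int, dendropy.Tree] = field(default_factory=dict)
    consensus_trees: dict[int, dendropy.Tree] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _pcoa(dist: np.ndarray, naxes: int) -> tuple[np.ndarray, np.ndarray]:
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    naxes = min(naxes, n)
    coords = np.zeros((n, naxes))
    for i in range(naxes):
        if w[i] > 1e-12:
            coords[:, i] = v[:, i] * np.sqrt(w[i])
    return coords, w


def embed_and_cluster(
    dist: np.ndarray,
    naxes: int = 4,
    nclust: int = 3,
) -> LandscapeResult:
    """PCoA embedding of a distance matrix + Ward clustering of the axes.

    Deterministic: classical MDS has no random initialization and Ward
    linkage with a fixed cut is exact.  Cluster ids are renumbered by first
    appearance so identical inputs always yield identical labelings.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if nclust > n:
        raise ValueError("more clusters requested than trees")
    coords, eigenvalues = _pcoa(dist, naxes)
    if np.allclose(dist, 0.0):
        warnings.warn("all trees coincide; clustering is degenerate", stacklevel=2)
        labels = np.ones(n, dtype=int)
    else:
        z = linkage(coords, method="ward")
        raw = fcluster(z, t=nclust, criterion="maxclust")
        # renumber by first appearance for determinism
        remap, labels = {}, np.empty(n, dtype=int)
        for i, r in enumerate(raw):
            if r not in remap:
                remap[r] = len(remap) + 1
            labels[i] = remap[r]
    return LandscapeResult(coordinates=coords, labels=labels, eigenvalues=eigenvalues)


def cluster_summary_trees(
    trees: list[dendropy.Tree],
    labels: np.ndarray,
    lam: float = 0.0,
    min_freq: float = 0.5,
) -> tuple[dict[int, dendropy.Tree], dict[int, dendropy.Tree]]:
    """Per-cluster median tree and majority-rule consensus.

    The median tree of a cluster is the member minimizing the sum of KC
    distances to all members (ties broken by lowest input index).
    """
    labels = np.asarray(labels)
    if len(labels) != len(trees):
        raise ValueError("labels and trees differ in length")
    dist = kc_distance_matrix(trees, lam)
    medians: dict[int, dendropy.Tree] = {}
    consensi: dict[int, dendropy.Tree] = {}
    for cl in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cl)
        if idx.size == 0:
            warnings.warn(f"cluster {cl} is empty; skipped", stacklevel=2)
            continue
        sums = dist[np.ix_(idx, idx)].sum(axis=1)
        medians[cl] = trees[int(idx[int(np.argmin(sums))])]
        consensi[cl] = consensus_tree([trees[i] for i in idx], min_freq=min_freq)
    return medians, consensi


def find_groves(
    trees: list[dendropy.Tree],
    lam: float = 0.0,
    naxes: int = 4,
    nclust: int = 3,
) -> LandscapeResult:
    """KC distances -> MDS -> Ward clusters -> per-cluster summary trees."""
    dist = kc_distance_matrix(trees, lam)
    result = embed_and_cluster(dist, naxes=naxes, nclust=nclust)
    medians, consensi = cluster_summary_trees(trees, result.labels, lam)
    result.median_trees = medians
    result.consensus_trees = consensi
    return result
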