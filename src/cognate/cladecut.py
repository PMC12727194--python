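"""Cutting a rooted tree into clades under a distance threshold.

Five methods are supported.  Four are clade-constrained — every cluster must
be exactly the leaf set of one subtree — and differ in the statistic bounded
by the threshold:

* ``avg_clade``      mean pairwise leaf-to-leaf path distance within the clade
* ``leaf_dist_max``  maximum clade-root-to-leaf distance
* ``leaf_dist_min``  minimum clade-root-to-leaf distance
* ``root_dist``      maximum leaf depth below the clade root, measured along
  rooted depth (numerically identical to ``leaf_dist_max`` on a rooted tree;
  kept as a distinct method name)

``single_linkage`` drops the clade constraint: clusters are connected
components of the graph joining leaves at path distance ≤ threshold.

For the clade-constrained methods the partition is the exact minimum-
cardinality one: since any clade strictly inside a subtree lies inside one
of its children, f(v) = 1 if clade(v) satisfies the constraint else
Σ f(children) is optimal, and the partition is recovered top-down by taking
every maximal valid clade.  Clusters of size 1 are relabeled −1
("unclassified").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp

METHODS = ("avg_clade", "leaf_dist_max", "leaf_dist_min", "root_dist", "single_linkage")
CLADE_METHODS = ("avg_clade", "leaf_dist_max", "leaf_dist_min", "root_dist")

UNCLASSIFIED = -1


@dataclass(frozen=True)
class CladeAssignment:
    """Leaf partition: labels ≥ 1 are clusters, −1 is unclassified.

    ``cut_tree`` guarantees every labeled cluster has ≥ 2 leaves (singletons
    become −1); k-means partitions may legitimately contain singleton
    clusters with labels ≥ 1.
    """

    labels: dict[str, int]
    method: str
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len({lab for lab in self.labels.values() if lab != UNCLASSIFIED})

    @property
    def n_unclassified(self) -> int:
        return sum(1 for lab in self.labels.values() if lab == UNCLASSIFIED)

    def unclassified_ratio(self, denominator: str = "clusters") -> float:
        """#(−1 leaves) divided by the cluster count (default) or leaf count."""
        if denominator == "clusters":
            return self.n_unclassified / self.n_clusters if self.n_clusters else float("nan")
        if denominator == "leaves":
            return self.n_unclassified / len(self.labels)
        raise ValueError(f"unknown denominator {denominator!r}")

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for leaf, lab in sorted(self.labels.items()):
            out.setdefault(lab, []).append(leaf)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["leaf_id", "clade_label"]
        )


@dataclass
class _NodeStats:
    leaves: list[str]
    leaf_dists: np.ndarray  # distance from this node to each leaf of its clade
    pair_sum: float  # sum of pairwise leaf-to-leaf path distances within clade

    @property
    def mean_pairwise(self) -> float:
        n = len(self.leaves)
        return 0.0 if n < 2 else self.pair_sum / (n * (n - 1) / 2)


def _collect_stats(tree: dendropy.Tree) -> dict[dendropy.Node, _NodeStats]:
    stats: dict[dendropy.Node, _NodeStats] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[node] = _NodeStats([node.taxon.label], np.zeros(1), 0.0)
            continue
        leaves: list[str] = []
        dists: list[np.ndarray] = []
        pair_sum = 0.0
        done: list[tuple[np.ndarray, int]] = []  # (child dists + edge, count)
        for child in node.child_nodes():
            cs = stats[child]
            edge = child.edge.length or 0.0
            dd = cs.leaf_dists + edge
            pair_sum += cs.pair_sum
            for prev_dd, prev_n in done:
                # cross-child pairs: all (x in prev, y in this child)
                pair_sum += float(prev_dd.sum()) * len(dd) + float(dd.sum()) * prev_n
            done.append((dd, len(dd)))
            leaves.extend(cs.leaves)
            dists.append(dd)
        stats[node] = _NodeStats(leaves, np.concatenate(dists), pair_sum)
    return stats


def _clade_ok(node: dendropy.Node, stats, method: str, threshold: float) -> bool:
    st = stats[node]
    if method == "avg_clade":
        return st.mean_pairwise <= threshold
    if method in ("leaf_dist_max", "root_dist"):
        return float(st.leaf_dists.max()) <= threshold
    if method == "leaf_dist_min":
        return float(st.leaf_dists.min()) <= threshold
    raise ValueError(f"unknown clade method {method!r}")


def _leaf_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, d


def cut_tree(tree: dendropy.Tree, method: str, threshold: float) -> CladeAssignment:
    """Partition the tree's leaves under ``method`` at ``threshold``.

    Clade-constrained methods require a rooted tree and return the
    minimum-cardinality partition into valid clades; singleton clusters are
    relabeled −1.  Cluster labels ≥ 1 are assigned deterministically in
    order of each cluster's smallest leaf label.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if isnan(threshold) or threshold < 0:
        raise ValueError("threshold must be >= 0")

    if method == "single_linkage":
        labels, d = _leaf_distance_matrix(tree)
        adj = sp.csr_matrix(d <= threshold)
        _, comp = sp.csgraph.connected_components(adj, directed=False)
        groups: dict[int, list[str]] = {}
        for leaf, c in zip(labels, comp):
            groups.setdefault(int(c), []).append(leaf)
        raw = list(groups.values())
    else:
        if not tree.is_rooted:
            raise ValueError(f"method {method!r} requires a rooted tree")
        stats = _collect_stats(tree)
        raw = []

        def collect(node: dendropy.Node) -> None:
            if _clade_ok(node, stats, method, threshold):
                raw.append(stats[node].leaves)
            else:
                for child in node.child_nodes():
                    collect(child)

        collect(tree.seed_node)

    clusters = sorted((sorted(c) for c in raw if len(c) >= 2), key=lambda c: c[0])
    labels_out: dict[str, int] = {}
    for idx, cluster in enumerate(clusters, start=1):
        for leaf in cluster:
            labels_out[leaf] = idx
    for c in raw:
        if len(c) == 1:
            labels_out[c[0]] = UNCLASSIFIED
    return CladeAssignment(labels=labels_out, method=method, threshold=threshold)


def sweep_thresholds(
    tree: dendropy.Tree,
    method: str,
    t_min: float = 0.05,
    t_max: float = 1.0,
    step: float = 0.05,
) -> pd.DataFrame:
    """Cut the tree over a threshold grid; one row per threshold.

    Columns: threshold, n_clusters, n_unclassified, ratio_by_clusters
    (−1 count over cluster count) and ratio_by_leaves (−1 count over leaf
    count).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    n_steps = int(round((t_max - t_min) / step)) + 1
    grid = [t_min + i * step for i in range(n_steps) if t_min + i * step <= t_max + 1e-12]
    rows = []
    for t in grid:
        ca = cut_tree(tree, method, t)
        rows.append(
            (
                round(t, 10),
                ca.n_clusters,
                ca.n_unclassified,
                ca.unclassified_ratio("clusters"),
                ca.unclassified_ratio("leaves"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["threshold", "n_clusters", "n_unclassified", "ratio_by_clusters", "ratio_by_leaves"],
    )
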