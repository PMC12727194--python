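"""Similarity graph construction and Markov clustering of neighborhood proteins.

Edges are weighted −log10(E-value) (capped) or bit-score.  MCL follows the
standard process: add self-loops, column-normalize, then alternate expansion
(matrix power), inflation (entrywise power + renormalization) and pruning
until the matrix stops changing; clusters are the connected components of
the converged nonzero structure.  Cluster IDs are assigned in order of
cluster size, 0 for the largest, ties broken by smallest member gene_id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from cognate.genome import GenomeTable
from cognate.homology import SimilarityHit

log = logging.getLogger(__name__)


class MclError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of gene_ids into clusters with size-ranked integer IDs."""

    membership: dict[str, int]
    sizes: dict[int, int]

    def __post_init__(self) -> None:
        counts: dict[int, int] = {}
        for cid in self.membership.values():
            counts[cid] = counts.get(cid, 0) + 1
        if counts != self.sizes:
            raise ValueError("sizes inconsistent with membership")
        ordered = [self.sizes[c] for c in sorted(self.sizes)]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("cluster sizes must be non-increasing in cluster_id")

    def members(self, cluster_id: int) -> list[str]:
        return sorted(g for g, c in self.membership.items() if c == cluster_id)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def build_graph(
    hits: Iterable[SimilarityHit],
    weighting: str = "neg_log_evalue",
    cap: float = 200.0,
) -> nx.Graph:
    """Undirected similarity graph; one edge per unordered pair, best weight kept."""
    if weighting not in ("neg_log_evalue", "bitscore"):
        raise ValueError(f"unknown weighting {weighting!r}")
    g = nx.Graph()
    for h in hits:
        if h.evalue < 0:
            raise ValueError(f"negative evalue on hit {h.query_id}->{h.subject_id}")
        if h.query_id == h.subject_id:
            continue
        if weighting == "neg_log_evalue":
            w = cap if h.evalue == 0 else min(-math.log10(h.evalue), cap)
        else:
            w = h.score
        if w <= 0:
            continue
        u, v = h.query_id, h.subject_id
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    return g


def mcl(
    graph: nx.Graph,
    inflation: float = 1.2,
    expansion: int = 2,
    prune_below: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
    on_iteration=None,
) -> list[frozenset[str]]:
    """Markov clustering; returns raw clusters (unranked).

    Self-loop weight is the node's maximum incident edge weight (1 for
    isolated nodes).  Convergence is the max-norm change of the stochastic
    matrix between rounds; non-convergence within ``max_iter`` raises
    :class:`MclError` carrying the change trace.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csr")
    m = np.asarray(a.todense(), dtype=float)
    loops = m.max(axis=1)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)

    trace: list[float] = []
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        np.power(m, inflation, out=m)
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune_below] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        if np.any(colsum == 0):  # pruning emptied a column; restore its self-loop
            dead = np.nonzero(colsum[0] == 0)[0]
            m[dead, dead] = 1.0
            colsum = m.sum(axis=0, keepdims=True)
        m /= colsum
        change = float(np.abs(m - prev).max())
        trace.append(change)
        if on_iteration is not None:
            on_iteration(m.copy())
        if change < tol:
            break
    else:
        raise MclError(f"MCL did not converge in {max_iter} iterations; trace={trace[-5:]}")

    structure = sp.csr_matrix((m + m.T) > 0)
    n_comp, labels = sp.csgraph.connected_components(structure, directed=False)
    clusters: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), set()).add(node)
    log.info("MCL: %d nodes -> %d clusters (inflation %.2f)", n, n_comp, inflation)
    return [frozenset(c) for c in clusters.values()]


def assign_cluster_ids(raw_clusters: Iterable[frozenset[str] | set[str]]) -> ClusterAssignment:
    """Size-ranked IDs: 0 = largest; ties broken by smallest member gene_id."""
    clusters = [frozenset(c) for c in raw_clusters]
    seen: set[str] = set()
    for c in clusters:
        if seen & c:
            raise ValueError(f"overlapping clusters: {sorted(seen & c)[:3]}")
        seen |= c
    ordered = sorted(clusters, key=lambda c: (-len(c), min(c)))
    membership = {g: cid for cid, c in enumerate(ordered) for g in c}
    sizes = {cid: len(c) for cid, c in enumerate(ordered)}
    return ClusterAssignment(membership=membership, sizes=sizes)


def cluster_neighborhood_proteins(
    seqs: Sequence[tuple[str, str]],
    params=None,
    inflation: float = 1.2,
    weighting: str = "neg_log_evalue",
) -> ClusterAssignment:
    """Convenience: all-against-all -> graph -> MCL -> ranked IDs.

    Genes with no significant similarity to any other gene become singleton
    clusters (they are added to the graph as isolated nodes first).
    """
    from cognate.homology import all_against_all

    hits = all_against_all(seqs, params)
    g = build_graph(hits, weighting=weighting)
    g.add_nodes_from(gid for gid, _ in seqs)
    raw = mcl(g, inflation=inflation)
    return assign_cluster_ids(raw)


def summarize_clusters(
    assignment: ClusterAssignment,
    genomes: Sequence[GenomeTable],
    taxonomy: Mapping[str, str] | None = None,
    annotations: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-cluster report: ID, gene count, strain count, optional labels."""
    strain_of = {g.gene_id: t.strain_id for t in genomes for g in t.genes()}
    rows = []
    for cid in sorted(assignment.sizes):
        members = assignment.members(cid)
        strains = {strain_of.get(g, "?") for g in members}
        row = {
            "cluster_id": cid,
            "gene_count": len(members),
            "strain_count": len(strains),
            "annotation": (annotations or {}).get(cid, ""),
        }
        if taxonomy is not None:
            taxa = sorted({taxonomy.get(s, "") for s in strains} - {""})
            row["taxa"] = ";".join(taxa)
        else:
            row["taxa"] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=["cluster_id", "gene_count", "strain_count", "annotation", "taxa"])
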