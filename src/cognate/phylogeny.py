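"""Alignment, Poisson-corrected distances, neighbor joining and tree utilities.

Distances are in substitutions/site under the Poisson correction
d = −ln(1 − p), with p the fraction of differing sites among the columns
where both sequences are ungapped (pairwise deletion; complete deletion
available).  Trees are dendropy Trees: neighbor joining is implemented here
(Q-criterion, standard branch-length formulas, lexicographic tie-break) and
midpoint rooting / Newick I/O delegate to dendropy.

The built-in progressive aligner is a deliberately small fallback for when
no externally computed MSA is supplied: a k-mer-distance guide tree followed
by profile–profile global alignment with affine gaps.  It guarantees a valid
MSA (degapping any row recovers its input exactly) but makes no claim of
parity with dedicated MSA programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from cognate.cladecut import CladeAssignment

log = logging.getLogger(__name__)

GAP = "-"
_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


class NewickParseError(ValueError):
    pass


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: id -> aligned row (residues + '-')."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1 or lengths == {0}:
            raise ValueError("all MSA rows must have equal, nonzero length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))


# ---------------------------------------------------------------------------
# progressive alignment


def _blosum_array() -> np.ndarray:
    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(_AA), len(_AA)))
    for i, x in enumerate(_AA):
        for j, y in enumerate(_AA):
            m[i, j] = b[x, y]
    return m


_B62 = _blosum_array()


def _profile_freqs(rows: list[str]) -> np.ndarray:
    length = len(rows[0])
    f = np.zeros((length, len(_AA)))
    for row in rows:
        for pos, ch in enumerate(row):
            if ch != GAP:
                f[pos, _AA_INDEX.get(ch, _AA_INDEX["X"])] += 1.0
    return f / len(rows)


def _align_profiles(
    rows_a: list[tuple[str, str]],
    rows_b: list[tuple[str, str]],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[tuple[str, str]]:
    """Global affine-gap alignment of two profiles; returns merged rows."""
    fa = _profile_freqs([r for _, r in rows_a])
    fb = _profile_freqs([r for _, r in rows_b])
    s = fa @ _B62 @ fb.T
    la, lb = s.shape
    neg = -1e30
    m = np.full((la + 1, lb + 1), neg)
    ix = np.full((la + 1, lb + 1), neg)  # consumes profile A (gap in B)
    iy = np.full((la + 1, lb + 1), neg)  # consumes profile B (gap in A)
    m[0, 0] = 0.0
    if la:
        ix[1:, 0] = -gap_open - gap_extend * np.arange(la)
    if lb:
        iy[0, 1:] = -gap_open - gap_extend * np.arange(lb)
    j_idx = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        m[i, 1:] = np.maximum.reduce([m[i - 1, :-1], ix[i - 1, :-1], iy[i - 1, :-1]]) + s[i - 1]
        ix[i, 1:] = np.maximum(m[i - 1, 1:] - gap_open, ix[i - 1, 1:] - gap_extend)
        # iy[i, j] = max(m[i, j-1] - open, iy[i, j-1] - ext), unrolled to a
        # prefix-max scan: iy[i, j] = max_{k<=j}(m[i, k-1] - open + k*ext) - j*ext
        a = m[i, :lb] - gap_open + gap_extend * j_idx
        iy[i, 1:] = np.maximum.accumulate(a) - gap_extend * j_idx

    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = la, lb
    state = int(np.argmax([m[i, j], ix[i, j], iy[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            for r, (_, row) in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r, (_, row) in zip(out_b, rows_b):
                r.append(row[j - 1])
            prev = np.array([m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1]])
            state = int(np.argmax(prev + 1e-12 * np.array([2, 1, 0])))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            for r, (_, row) in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r in out_b:
                r.append(GAP)
            state = 0 if m[i - 1, j] - gap_open >= ix[i - 1, j] - gap_extend - 1e-12 else 1
            i -= 1
        elif state == 2 and j > 0:
            for r in out_a:
                r.append(GAP)
            for r, (_, row) in zip(out_b, rows_b):
                r.append(row[j - 1])
            state = 0 if m[i, j - 1] - gap_open >= iy[i, j - 1] - gap_extend - 1e-12 else 2
            j -= 1
        else:  # boundary: forced moves
            state = 1 if i > 0 else 2
    merged = [(sid, "".join(reversed(r))) for (sid, _), r in zip(rows_a, out_a)]
    merged += [(sid, "".join(reversed(r))) for (sid, _), r in zip(rows_b, out_b)]
    return merged


def _kmer_distance(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    from collections import Counter

    counters = [Counter(s[i : i + k] for i in range(max(1, len(s) - k + 1))) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = min(sum(counters[i].values()), sum(counters[j].values()))
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return d


def progressive_align(seqs: Sequence[tuple[str, str]]) -> Msa:
    """Progressive MSA: average-linkage guide tree on k-mer distances, then
    profile–profile affine-gap merges in guide-tree order."""
    if len(seqs) < 2:
        raise ValueError("progressive_align needs at least 2 sequences")
    ids = [sid for sid, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence IDs")
    for sid, s in seqs:
        if not s:
            raise ValueError(f"empty sequence {sid!r}")
    d = _kmer_distance([s for _, s in seqs])
    n = len(seqs)
    profiles: dict[int, list[tuple[str, str]]] = {i: [list(seqs)[i]] for i in range(n)}
    if n == 2:
        merged = _align_profiles(profiles[0], profiles[1])
    else:
        cond = d[np.triu_indices(n, k=1)]
        z = linkage(cond, method="average")
        for step, (a, b, _dist, _cnt) in enumerate(z):
            merged = _align_profiles(profiles.pop(int(a)), profiles.pop(int(b)))
            profiles[n + step] = merged
    rows = dict(merged)
    for sid, s in seqs:  # degap identity is structural; assert cheaply anyway
        assert rows[sid].replace(GAP, "") == s, f"aligner corrupted sequence {sid}"
    return Msa(rows={sid: rows[sid] for sid, _ in seqs})


# ---------------------------------------------------------------------------
# distances


class SaturatedPairError(ValueError):
    pass


def poisson_distance_matrix(
    msa: Msa,
    deletion: str = "pairwise",
    cap_saturated: bool = False,
) -> DistanceMatrix:
    """Poisson-corrected distances d = −ln(1 − p) from an MSA.

    Under pairwise deletion p is computed per pair over the columns where
    both rows are ungapped; under complete deletion only columns ungapped in
    every row are used.  A pair with no shared ungapped column is an error,
    as is a saturated pair (p = 1) unless ``cap_saturated`` caps p at
    1 − 1/(shared sites + 1).

    Ambiguous residues (X, B, Z, ...) are compared literally.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    labels = tuple(msa.rows)
    arr = np.array([list(msa.rows[l]) for l in labels])
    nongap = arr != GAP
    if deletion == "complete":
        keep = nongap.all(axis=0)
        if not keep.any():
            raise SaturatedPairError("complete deletion removed every column")
        arr = arr[:, keep]
        nongap = nongap[:, keep]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            shared = int(both.sum())
            if shared == 0:
                raise SaturatedPairError(
                    f"no mutually ungapped sites for pair ({labels[i]!r}, {labels[j]!r})"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / shared
            if p >= 1.0:
                if not cap_saturated:
                    raise SaturatedPairError(
                        f"saturated pair ({labels[i]!r}, {labels[j]!r}): p = 1"
                    )
                p = 1.0 - 1.0 / (shared + 1)
            d[i, j] = d[j, i] = -np.log1p(-p)
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ (Saitou–Nei) with deterministic lexicographic tie-breaks.

    Returns an unrooted dendropy tree.  Negative branch-length estimates are
    clamped to 0 and the deficit logged.  Ties in the Q criterion are broken
    by the lexicographically smallest (smallest-leaf-label) pair.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    keys: dict[int, str] = {}
    dist: dict[tuple[int, int], float] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes[i] = node
        keys[i] = lab
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.d[i, j])

    def d_of(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            log.debug("NJ: clamped negative branch %.3g on join (%s,%s)", x, a, b)
            return 0.0
        return x

    active = list(range(n))
    next_id = n
    while len(active) > 2:
        na = len(active)
        r = {i: sum(d_of(i, j) for j in active if j != i) for i in active}
        best = None
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                q = (na - 2) * d_of(i, j) - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = d_of(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (na - 2))
        lj = dij - li
        li = clamp(li, keys[i], keys[j])
        lj = clamp(lj, keys[i], keys[j])
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        keys[next_id] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = (d_of(i, k) + d_of(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j = active
    dij = d_of(i, j)
    if n == 2:
        root = dendropy.Node()
        root.add_child(nodes[i])
        nodes[i].edge.length = dij / 2
        root.add_child(nodes[j])
        nodes[j].edge.length = dij / 2
    else:
        # attach the remaining node to the internal one by the full edge
        internal, other = (i, j) if nodes[i].taxon is None else (j, i)
        root = nodes[internal]
        root.add_child(nodes[other])
        nodes[other].edge.length = max(dij, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    The input is not modified.  If all branch lengths are zero the tree is
    rooted at its current seed node with a warning.
    """
    rooted = tree.clone(depth=1)
    pdm = rooted.phylogenetic_distance_matrix()
    taxa = list(rooted.taxon_namespace)
    diameter = max(
        (pdm.patristic_distance(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1 :]),
        default=0.0,
    )
    if diameter <= 0:
        log.warning("midpoint_root: all path lengths are zero; rooting at current seed node")
        rooted.is_rooted = True
        return rooted
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def kmeans_partition(dm: DistanceMatrix, k: int, seed: int, n_init: int = 10) -> CladeAssignment:
    """k-means over the rows of the pairwise distance matrix.

    Each sequence is represented by its vector of distances to all sequences;
    k-means++ initialization from ``seed``, best of ``n_init`` restarts.
    Labels are 1..k (this method produces no −1 labels); label order is
    deterministic (by smallest member sequence id).
    """
    from sklearn.cluster import KMeans

    n = len(dm.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(dm.d)
    groups: dict[int, list[str]] = {}
    for lab, raw_lab in zip(dm.labels, raw):
        groups.setdefault(int(raw_lab), []).append(lab)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    labels = {leaf: idx + 1 for idx, group in enumerate(ordered) for leaf in group}
    return CladeAssignment(labels=labels, method="kmeans", threshold=float("nan"))


# ---------------------------------------------------------------------------
# Newick I/O


def newick_write(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths; metacharacter-containing labels quoted."""
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=False,
        suppress_item_comments=False,
        real_value_format_specifier=".17g",
    )


def newick_read(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree (underscores preserved)."""
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # noqa: BLE001 - uniform error type for callers
        raise NewickParseError(f"malformed Newick: {exc}") from exc


def tree_from_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return newick_read(fh.read())


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]
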