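"""Alignment, Poisson distances, NJ, rooting, k-means and Newick I/O."""

import math

import dendropy
import numpy as np
import pytest

from cognate.phylogeny import (
    DistanceMatrix,
    Msa,
    SaturatedPairError,
    NewickParseError,
    kmeans_partition,
    leaf_labels,
    midpoint_root,
    neighbor_joining,
    newick_read,
    newick_write,
    poisson_distance_matrix,
    progressive_align,
)


def _patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


def _random_additive(rng: np.random.Generator, n: int):
    """A random binary tree with random edge lengths and its path distances."""
    from cognate.simulate import simulate_strain_tree

    tree = simulate_strain_tree(n, 1.0, rng)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    dists = _patristic(tree)
    labels = tuple(sorted({a for a, _ in dists} | {b for _, b in dists}))
    d = np.zeros((n, n))
    for (a, b), val in dists.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = val
    return tree, DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------- alignment


def test_progressive_align_identical_pair_is_gapless():
    msa = progressive_align([("a", "MKVLITG"), ("b", "MKVLITG")])
    assert msa.rows["a"] == "MKVLITG"
    assert msa.rows["b"] == "MKVLITG"


def test_progressive_align_single_gap_and_degap_identity():
    msa = progressive_align([("x", "ACDEF"), ("y", "ACEF")])
    assert msa.degapped("x") == "ACDEF"
    assert msa.degapped("y") == "ACEF"
    assert msa.rows["y"].count("-") == 1


def test_progressive_align_equal_row_lengths(random_protein):
    seqs = [(f"s{i}", random_protein(30 + 7 * i)) for i in range(5)]
    msa = progressive_align(seqs)
    lengths = {len(row) for row in msa.rows.values()}
    assert len(lengths) == 1
    for sid, seq in seqs:
        assert msa.degapped(sid) == seq


def test_progressive_align_rejects_single_sequence():
    with pytest.raises(ValueError):
        progressive_align([("only", "MKV")])


# ---------------------------------------------------------------- distances


def test_poisson_distance_identical_rows():
    msa = Msa(rows={"a": "MKVLITG", "b": "MKVLITG"})
    dm = poisson_distance_matrix(msa)
    assert dm.d[0, 1] == 0.0


def test_poisson_distance_half_differing():
    # 10 mutually ungapped sites, 5 differ -> d = -ln(0.5)
    a = "AAAAAAAAAA"
    b = "AAAAACCCCC"
    dm = poisson_distance_matrix(Msa(rows={"a": a, "b": b}))
    assert dm.d[0, 1] == pytest.approx(-math.log(0.5), rel=1e-12)


def test_poisson_distance_pairwise_deletion_ignores_gap_columns():
    # gapped columns excluded pair-by-pair: 4 shared sites, 1 differs
    msa = Msa(rows={"a": "MK-VLA", "b": "MKW-LC"})
    dm = poisson_distance_matrix(msa, deletion="pairwise")
    assert dm.d[0, 1] == pytest.approx(-math.log(1 - 0.25))


def test_poisson_distance_no_overlap_errors():
    msa = Msa(rows={"a": "MK--", "b": "--VL"})
    with pytest.raises(SaturatedPairError, match="a"):
        poisson_distance_matrix(msa)


def test_poisson_distance_saturated_pair():
    msa = Msa(rows={"a": "AAAA", "b": "CCCC"})
    with pytest.raises(SaturatedPairError):
        poisson_distance_matrix(msa)
    dm = poisson_distance_matrix(msa, cap_saturated=True)
    assert np.isfinite(dm.d[0, 1])


def test_poisson_distance_small_p_limit():
    # d/p -> 1 as p -> 0: check at p = 1e-6 via the formula directly
    p = 1e-6
    assert -math.log1p(-p) / p == pytest.approx(1.0, abs=1e-5)


def test_poisson_complete_deletion():
    msa = Msa(rows={"a": "MKVL", "b": "MKV-", "c": "MKVA"})
    dm = poisson_distance_matrix(msa, deletion="complete")
    # last column dropped for every pair, a == c on the first three
    assert dm.d[0, 2] == 0.0


# ----------------------------------------------------------------------- NJ


def test_nj_two_taxa_split_symmetrically():
    dm = DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, 0.4], [0.4, 0.0]]))
    tree = neighbor_joining(dm)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}


def test_nj_three_taxa_closed_form():
    dab, dac, dbc = 0.6, 0.9, 0.7
    dm = DistanceMatrix(
        labels=("a", "b", "c"),
        d=np.array([[0, dab, dac], [dab, 0, dbc], [dac, 0.7, 0]], dtype=float),
    )
    tree = neighbor_joining(dm)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((dab + dac - dbc) / 2)
    assert lengths["b"] == pytest.approx((dab + dbc - dac) / 2)
    assert lengths["c"] == pytest.approx((dac + dbc - dab) / 2)


@pytest.mark.parametrize("n", [4, 6, 8, 10])
def test_nj_recovers_additive_distances(n):
    rng = np.random.default_rng(n)
    for _ in range(5):
        _, dm = _random_additive(rng, n)
        nj = neighbor_joining(dm)
        rebuilt = _patristic(nj)
        for (a, b), val in rebuilt.items():
            i, j = dm.labels.index(a), dm.labels.index(b)
            assert val == pytest.approx(dm.d[i, j], abs=1e-9)


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, 1.0], [2.0, 0.0]]))


# ------------------------------------------------------------------ rooting


def test_midpoint_root_two_leaves():
    tree = newick_read("(a:0.1,b:0.3);")
    rooted = midpoint_root(tree)
    depths = {}
    for leaf in rooted.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    assert depths["a"] == pytest.approx(0.2)
    assert depths["b"] == pytest.approx(0.2)


def test_midpoint_root_on_long_branch():
    # star with pendants 1, 1, 4: diameter 5, midpoint on c's branch
    tree = newick_read("(a:1,b:1,c:4);")
    rooted = midpoint_root(tree)
    root_children = rooted.seed_node.child_nodes()
    # one child is leaf c at depth 2.5
    leaf_depths = {}
    for leaf in rooted.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        leaf_depths[leaf.taxon.label] = d
    assert leaf_depths["c"] == pytest.approx(2.5)
    assert max(leaf_depths.values()) == pytest.approx(2.5)


def test_midpoint_root_preserves_path_lengths():
    rng = np.random.default_rng(11)
    tree, _ = _random_additive(rng, 7)
    before = _patristic(tree)
    rooted = midpoint_root(tree)
    after = _patristic(rooted)
    for pair, val in before.items():
        assert after[pair] == pytest.approx(val, abs=1e-9)


def test_midpoint_root_idempotent_topology():
    tree = newick_read("((a:0.1,b:0.2):0.3,(c:0.1,d:0.4):0.2);")
    once = midpoint_root(tree)
    twice = midpoint_root(once)
    assert _patristic(once) == pytest.approx(_patristic(twice))


# ------------------------------------------------------------------ k-means


def test_kmeans_extremes():
    rng = np.random.default_rng(0)
    n = 6
    d = np.abs(rng.normal(0.5, 0.1, (n, n)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    dm = DistanceMatrix(labels=tuple(f"t{i}" for i in range(n)), d=d)
    assert set(kmeans_partition(dm, 1, seed=0).labels.values()) == {1}
    assert sorted(kmeans_partition(dm, n, seed=0).labels.values()) == list(range(1, n + 1))
    with pytest.raises(ValueError):
        kmeans_partition(dm, n + 1, seed=0)


def test_kmeans_recovers_separated_blocks():
    labels = tuple(f"a{i}" for i in range(4)) + tuple(f"b{i}" for i in range(4))
    d = np.full((8, 8), 1.0)
    d[:4, :4] = 0.01
    d[4:, 4:] = 0.01
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(labels=labels, d=d)
    got = kmeans_partition(dm, 2, seed=1)
    groups = {}
    for leaf, lab in got.labels.items():
        groups.setdefault(lab, set()).add(leaf)
    assert set(map(frozenset, groups.values())) == {
        frozenset(labels[:4]), frozenset(labels[4:])
    }


def test_kmeans_reproducible():
    rng = np.random.default_rng(5)
    _, dm = _random_additive(rng, 9)
    a = kmeans_partition(dm, 3, seed=123)
    b = kmeans_partition(dm, 3, seed=123)
    assert a.labels == b.labels


# ------------------------------------------------------------------- Newick


@pytest.mark.parametrize("text", ["(a:0.1,b:0.2);", "((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.2);"])
def test_newick_round_trip(text):
    tree = newick_read(text)
    again = newick_read(newick_write(tree))
    assert sorted(leaf_labels(tree)) == sorted(leaf_labels(again))
    assert _patristic(tree) == pytest.approx(_patristic(again), abs=1e-9)


def test_newick_label_with_pipe_survives():
    tree = newick_read("('x|1':0.1,'y|2':0.2);")
    text = newick_write(tree)
    again = newick_read(text)
    assert sorted(leaf_labels(again)) == ["x|1", "y|2"]


def test_newick_malformed_raises():
    with pytest.raises(NewickParseError):
        newick_read("((a:0.1,b:0.2;")
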