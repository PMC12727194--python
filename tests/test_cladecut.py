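"""Clade cutting vs brute-force enumeration of all valid partitions."""

import itertools

import dendropy
import numpy as np
import pytest

from cognate.cladecut import CLADE_METHODS, METHODS, cut_tree, sweep_thresholds
from cognate.phylogeny import newick_read
from cognate.simulate import simulate_strain_tree


def random_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    tree = simulate_strain_tree(n_leaves, 1.0, rng)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.02, 0.6))
    tree.is_rooted = True
    return tree


def _tree_tables(tree: dendropy.Tree):
    """Leaf depths, pairwise path distances, per-node leaf sets — computed
    from scratch (no reuse of the implementation's traversal)."""
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    dist = {
        (a, b): pdm.patristic_distance(taxa[a], taxa[b])
        for a in labels
        for b in labels
    }
    clades = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset({node.taxon.label})
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.child_nodes()))
    leaf_depth = {lf.taxon.label: depth[lf] for lf in tree.leaf_node_iter()}
    node_depth = {clades[n]: depth[n] for n in tree.preorder_node_iter()}
    return labels, dist, clades, leaf_depth, node_depth


def _clade_valid(leafset, method, threshold, dist, leaf_depth, clade_depth):
    leaves = sorted(leafset)
    if len(leaves) == 1:
        return True
    if method == "avg_clade":
        pairs = list(itertools.combinations(leaves, 2))
        return sum(dist[p] for p in pairs) / len(pairs) <= threshold + 1e-12
    # root-to-leaf statistics: clade root depth subtracted from leaf depths
    vals = [leaf_depth[l] - clade_depth for l in leaves]
    if method in ("leaf_dist_max", "root_dist"):
        return max(vals) <= threshold + 1e-12
    if method == "leaf_dist_min":
        return min(vals) <= threshold + 1e-12
    raise AssertionError(method)


def _all_clade_partitions(node, clades):
    """Every partition of the node's leaves into disjoint clades."""
    own = [[clades[node]]]
    if node.is_leaf():
        return own
    child_parts = [_all_clade_partitions(c, clades) for c in node.child_nodes()]
    for combo in itertools.product(*child_parts):
        own.append([cl for part in combo for cl in part])
    return own


def brute_force_min_parts(tree, method, threshold):
    labels, dist, clades, leaf_depth, node_depth = _tree_tables(tree)
    if method == "single_linkage":
        # naive transitive closure over the threshold graph
        groups = {l: {l} for l in labels}
        changed = True
        while changed:
            changed = False
            for a in labels:
                for b in labels:
                    if a != b and dist[(a, b)] <= threshold + 1e-12:
                        if groups[a] is not groups[b]:
                            merged = groups[a] | groups[b]
                            for m in merged:
                                groups[m] = merged
                            changed = True
        return len({id(g) for g in groups.values()}), {frozenset(g) for g in groups.values()}
    best = None
    best_parts = None
    for partition in _all_clade_partitions(tree.seed_node, clades):
        ok = all(
            _clade_valid(cl, method, threshold, dist, leaf_depth, node_depth[cl])
            for cl in partition
        )
        if ok and (best is None or len(partition) < best):
            best = len(partition)
            best_parts = {frozenset(cl) for cl in partition}
    return best, best_parts


def _total_parts(assignment):
    return assignment.n_clusters + assignment.n_unclassified


def check_cut_against_brute_force(method: str, n_trials: int, seed: int) -> None:
    """Shared oracle harness: minimal-cardinality + constraint satisfaction."""
    rng = np.random.default_rng(seed)
    for trial in range(n_trials):
        tree = random_tree(rng, int(rng.integers(3, 8)))
        diameter = max(_tree_tables(tree)[1].values())
        threshold = float(rng.uniform(0.0, 1.1 * diameter))
        got = cut_tree(tree, method, threshold)
        want_count, _ = brute_force_min_parts(tree, method, threshold)
        assert _total_parts(got) == want_count, f"{method} trial {trial}"
        # every emitted cluster satisfies the method's constraint
        labels, dist, clades, leaf_depth, node_depth = _tree_tables(tree)
        clade_sets = {frozenset(c) for c in clades.values()}
        for lab, members in got.clusters().items():
            if lab == -1:
                continue
            ms = frozenset(members)
            if method != "single_linkage":
                assert ms in clade_sets, "cluster is not a clade"
                assert _clade_valid(ms, method, threshold, dist, leaf_depth, node_depth[ms])


@pytest.mark.parametrize("method", METHODS)
def test_cut_tree_matches_brute_force(method):
    """Minimal-cardinality partitions on random trees with ≤ 7 leaves."""
    check_cut_against_brute_force(method, n_trials=30, seed=1000 + METHODS.index(method))


def test_single_linkage_partitions_match_closure():
    rng = np.random.default_rng(99)
    for _ in range(20):
        tree = random_tree(rng, 6)
        threshold = float(rng.uniform(0.05, 1.0))
        got = cut_tree(tree, "single_linkage", threshold)
        _, want_parts = brute_force_min_parts(tree, "single_linkage", threshold)
        got_parts = {
            frozenset(m) for m in got.clusters().values()
        } if -1 not in got.clusters() else (
            {frozenset(m) for lab, m in got.clusters().items() if lab != -1}
            | {frozenset({l}) for l in got.clusters().get(-1, [])}
        )
        assert got_parts == want_parts


def test_star_tree_single_cluster():
    tree = newick_read("(a:0.1,b:0.1,c:0.1,d:0.1);")
    tree.is_rooted = True
    got = cut_tree(tree, "avg_clade", 1.0)
    assert got.n_clusters == 1
    assert set(got.labels.values()) == {1}


def test_two_distant_cherries_split():
    tree = newick_read("((a:0.05,b:0.05):10,(c:0.05,d:0.05):10);")
    tree.is_rooted = True
    got = cut_tree(tree, "avg_clade", 0.2)
    groups = {frozenset(m) for lab, m in got.clusters().items() if lab != -1}
    assert groups == {frozenset({"a", "b"}), frozenset({"c", "d"})}


def test_threshold_zero_unclassifies_everything():
    tree = newick_read("((a:0.1,b:0.2):0.3,c:0.4);")
    tree.is_rooted = True
    got = cut_tree(tree, "avg_clade", 0.0)
    assert got.n_clusters == 0
    assert set(got.labels.values()) == {-1}
    assert got.n_unclassified == 3


def test_unrooted_tree_rejected_for_clade_methods():
    tree = newick_read("(a:0.1,b:0.2,c:0.3);")
    tree.is_rooted = False
    with pytest.raises(ValueError, match="rooted"):
        cut_tree(tree, "avg_clade", 0.5)
    cut_tree(tree, "single_linkage", 0.5)  # unrooted fine here


def test_unknown_method_rejected():
    tree = newick_read("(a:0.1,b:0.2);")
    with pytest.raises(ValueError):
        cut_tree(tree, "med_clade", 0.5)


def test_sweep_grid_and_monotonicity():
    rng = np.random.default_rng(17)
    tree = random_tree(rng, 12)
    for method in METHODS:
        table = sweep_thresholds(tree, method, 0.05, 1.0, 0.05)
        assert len(table) == 20
        total = table.n_clusters + table.n_unclassified
        assert (total.diff().dropna() <= 0).all(), f"{method}: part count not monotone"


def test_sweep_large_threshold_single_cluster():
    tree = newick_read("((a:0.01,b:0.01):0.01,(c:0.01,d:0.01):0.01);")
    tree.is_rooted = True
    table = sweep_thresholds(tree, "avg_clade", 0.5, 1.0, 0.25)
    last = table.iloc[-1]
    assert last.n_clusters == 1 and last.n_unclassified == 0
    assert last.ratio_by_clusters == 0.0


def test_sweep_rejects_bad_step():
    tree = newick_read("(a:0.1,b:0.2);")
    tree.is_rooted = True
    with pytest.raises(ValueError):
        sweep_thresholds(tree, "avg_clade", step=0.0)
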