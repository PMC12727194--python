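"""Per-clade conserved gene cluster lists (GCLs) and reference-based evaluation.

For each tree clade of target homologs, the member genes of the clade's
anchors' neighborhoods are pooled (deduplicated by gene_id), counted per
gene cluster, and divided by the number of distinct strains contributing
anchors to the clade — the criteria score.  Cluster IDs whose score passes
the cutoff (strictly > 1.0 by default; ≥, and relaxed cutoffs such as 0.9,
available) form the clade's GCL, written as ascending IDs joined by '|'.

Clade assignments can additionally be scored against an external reference
classification (a leaf → class table): per clade the number of distinct
reference classes it contains, per class the number of distinct clades
containing it, each total normalized by the clade count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cognate.cladecut import UNCLASSIFIED, CladeAssignment
from cognate.clustering import ClusterAssignment
from cognate.genome import Neighborhood

COMPARISONS = ("strict_greater", "greater_or_equal")


@dataclass(frozen=True)
class GclRow:
    clade_label: int
    anchor_gene_ids: tuple[str, ...]
    n_strains: int
    cluster_counts: dict[int, int]
    scores: dict[int, float]
    conserved_ids: tuple[int, ...]

    @property
    def gcl_string(self) -> str:
        return format_gcl(self)


def format_gcl(row: GclRow) -> str:
    """Ascending cluster IDs joined by '|'; empty GCL -> empty string."""
    return "|".join(str(c) for c in sorted(row.conserved_ids))


def build_gcl(
    clades: CladeAssignment,
    neighborhoods: Sequence[Neighborhood],
    clusters: ClusterAssignment,
    gene_index: Mapping[str, str],
    cutoff: float = 1.0,
    comparison: str = "strict_greater",
) -> list[GclRow]:
    """Criteria-score the gene clusters of each clade's pooled neighborhoods.

    ``gene_index`` maps gene_id -> strain_id.  Leaves labeled −1 are
    excluded.  Every clade leaf must be the anchor of some neighborhood; the
    strain count is over the anchors' strains.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {COMPARISONS}")
    nb_by_anchor = {nb.anchor_gene_id: nb for nb in neighborhoods}
    rows: list[GclRow] = []
    for clade_label, leaves in sorted(clades.clusters().items()):
        if clade_label == UNCLASSIFIED:
            continue
        missing = [l for l in leaves if l not in nb_by_anchor]
        if missing:
            raise KeyError(f"clade {clade_label}: no neighborhood for anchors {missing[:5]}")
        pooled: set[str] = set()
        for leaf in leaves:
            pooled.update(nb_by_anchor[leaf].member_gene_ids)
        counts: dict[int, int] = {}
        for gid in pooled:
            cid = clusters.membership[gid]
            counts[cid] = counts.get(cid, 0) + 1
        n_strains = len({gene_index[l] for l in leaves})
        scores = {cid: c / n_strains for cid, c in counts.items()}
        if comparison == "strict_greater":
            conserved = tuple(sorted(c for c, s in scores.items() if s > cutoff))
        else:
            conserved = tuple(sorted(c for c, s in scores.items() if s >= cutoff))
        rows.append(
            GclRow(
                clade_label=clade_label,
                anchor_gene_ids=tuple(sorted(leaves)),
                n_strains=n_strains,
                cluster_counts=dict(sorted(counts.items())),
                scores=dict(sorted(scores.items())),
                conserved_ids=conserved,
            )
        )
    return rows


def gcl_frame(rows: Iterable[GclRow], cutoff: float = 1.0) -> pd.DataFrame:
    """Long-form gcl.tsv layout: one row per (clade, cluster)."""
    out = []
    for r in rows:
        for cid, count in r.cluster_counts.items():
            out.append(
                (
                    r.clade_label,
                    len(r.anchor_gene_ids),
                    r.n_strains,
                    cid,
                    count,
                    r.scores[cid],
                    cid in r.conserved_ids,
                )
            )
    return pd.DataFrame(
        out,
        columns=["clade_label", "n_anchors", "n_strains", "cluster_id", "count", "score", "conserved"],
    )


def gcl_summary_frame(rows: Iterable[GclRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.clade_label, r.gcl_string) for r in rows],
        columns=["clade_label", "gcl_string"],
    )


@dataclass(frozen=True)
class EvaluationResult:
    per_clade_class_counts: dict[int, int]
    per_class_clade_counts: dict[str, int]
    cluster2h_class_total: int
    h_class2cluster_total: int
    cluster2h_class_ratio: float
    h_class2cluster_ratio: float

    @property
    def combined_total(self) -> int:
        return self.cluster2h_class_total + self.h_class2cluster_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("cluster2h_class_total", self.cluster2h_class_total),
                ("h_class2cluster_total", self.h_class2cluster_total),
                ("cluster2h_class_ratio", self.cluster2h_class_ratio),
                ("h_class2cluster_ratio", self.h_class2cluster_ratio),
                ("combined_total", self.combined_total),
            ],
            columns=["metric", "value"],
        )


def evaluate_against_reference(
    clades: CladeAssignment,
    ref_classes: Mapping[str, str],
    include_unclassified: bool = False,
    subtract_one: bool = False,
) -> EvaluationResult:
    """Score a clade assignment against a reference leaf classification.

    Per clade, the count is the number of distinct reference classes among
    its leaves; per class, the number of distinct clades containing it.  A
    perfect 1:1 correspondence gives both ratios 1.0 (each total equals the
    clade count).  ``subtract_one`` switches to excess counts (distinct − 1).
    Leaves labeled −1 are excluded unless ``include_unclassified``.
    """
    leaves = {
        leaf: lab
        for leaf, lab in clades.labels.items()
        if include_unclassified or lab != UNCLASSIFIED
    }
    missing = sorted(l for l in leaves if l not in ref_classes)
    if missing:
        raise KeyError(f"leaves without a reference class: {missing[:10]}")

    clade_classes: dict[int, set[str]] = {}
    class_clades: dict[str, set[int]] = {}
    for leaf, lab in leaves.items():
        cls = ref_classes[leaf]
        clade_classes.setdefault(lab, set()).add(cls)
        class_clades.setdefault(cls, set()).add(lab)

    sub = 1 if subtract_one else 0
    per_clade = {lab: max(len(cs) - sub, 0) for lab, cs in sorted(clade_classes.items())}
    per_class = {cls: max(len(cl) - sub, 0) for cls, cl in sorted(class_clades.items())}
    n_clades = len(clade_classes)
    c2h = sum(per_clade.values())
    h2c = sum(per_class.values())
    return EvaluationResult(
        per_clade_class_counts=per_clade,
        per_class_clade_counts=per_class,
        cluster2h_class_total=c2h,
        h_class2cluster_total=h2c,
        cluster2h_class_ratio=c2h / n_clades if n_clades else float("nan"),
        h_class2cluster_ratio=h2c / n_clades if n_clades else float("nan"),
    )


def read_reference_classes(path) -> dict[str, str]:
    """2-column TSV: sequence_id <tab> class label (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("reference class table needs 2 columns")
    first = df.iloc[0]
    if first[0].lower() in ("leaf_id", "sequence_id", "id"):
        df = df.iloc[1:]
    return dict(zip(df[0], df[1]))


# ---------------------------------------------------------------------------
# tree annotation

_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def annotate_tree(
    tree,
    clades: CladeAssignment,
    gcl: Sequence[GclRow],
    render_path=None,
) -> tuple[str, pd.DataFrame]:
    """Embed clade labels as internal-node comments; build a color/GCL legend.

    Returns the annotated Newick string and the legend table (clade_label,
    color, n_leaves, gcl_string).  Colors cycle a fixed palette by clade
    label, so re-runs are byte-identical.  If ``render_path`` is given, a
    simple rectangular tree figure colored by clade is written there.
    """
    from cognate.phylogeny import newick_write

    annotated = tree.clone(depth=1)
    gcl_by_label = {r.clade_label: r for r in gcl}
    legend_rows = []
    taxa = {t.label: t for t in annotated.taxon_namespace}
    for lab, leaves in sorted(clades.clusters().items()):
        if lab == UNCLASSIFIED:
            continue
        mrca = annotated.mrca(taxa=[taxa[l] for l in leaves if l in taxa])
        if mrca is not None:
            mrca.comments.append(f"clade={lab}")
        row = gcl_by_label.get(lab)
        legend_rows.append(
            (
                lab,
                _PALETTE[(lab - 1) % len(_PALETTE)],
                len(leaves),
                row.gcl_string if row is not None else "",
            )
        )
    legend = pd.DataFrame(legend_rows, columns=["clade_label", "color", "n_leaves", "gcl_string"])
    newick = newick_write(annotated)
    if render_path is not None:
        _render(tree, clades, legend, render_path)
    return newick, legend


def _render(tree, clades: CladeAssignment, legend: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    color_of = dict(zip(legend["clade_label"], legend["color"]))
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    y_of = {leaf: i for i, leaf in enumerate(leaves)}
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
    ys: dict = {}
    fig, ax = plt.subplots(figsize=(6, max(2, 0.22 * len(leaves))))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            ys[node] = y_of[label]
            lab = clades.labels.get(label, UNCLASSIFIED)
            color = color_of.get(lab, "#999999")
            ax.plot([depth[node.parent_node] if node.parent_node else 0, depth[node]],
                    [ys[node]] * 2, color=color, lw=1.2)
            ax.text(depth[node], ys[node], f" {label}", va="center", fontsize=5)
        else:
            child_ys = [ys[c] for c in node.child_nodes()]
            ys[node] = sum(child_ys) / len(child_ys)
            x0 = depth[node.parent_node] if node.parent_node else 0
            ax.plot([x0, depth[node]], [ys[node]] * 2, color="#444444", lw=1.0)
            ax.plot([depth[node]] * 2, [min(child_ys), max(child_ys)], color="#444444", lw=1.0)
    ax.set_yticks([])
    ax.set_xlabel("substitutions/site")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
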