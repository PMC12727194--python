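"""End-to-end workflow: genomes + query -> neighborhoods -> clusters -> tree ->
clades -> per-clade conserved gene cluster lists.

Stages write their outputs as TSV/FASTA/Newick files into the run directory
and record a digest chain in ``manifest.json``; re-running with unchanged
inputs and parameters skips completed stages, and changing a parameter
reruns only the stages depending on it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from cognate import __version__
from cognate.cladecut import CladeAssignment, cut_tree, sweep_thresholds
from cognate.clustering import (
    ClusterAssignment,
    assign_cluster_ids,
    build_graph,
    mcl,
    summarize_clusters,
)
from cognate.conservation import (
    annotate_tree,
    build_gcl,
    evaluate_against_reference,
    gcl_frame,
    gcl_summary_frame,
    read_reference_classes,
)
from cognate.genome import (
    GenomeTable,
    Neighborhood,
    extract_neighborhood,
    genes_frame,
    neighborhoods_frame,
    read_genbank,
    read_gff_fasta,
)
from cognate.homology import SearchParams, all_against_all, hits_frame, search_homologs
from cognate.phylogeny import (
    Msa,
    midpoint_root,
    neighbor_joining,
    newick_write,
    poisson_distance_matrix,
    progressive_align,
    tree_from_file,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the method's standard settings."""

    genome_dir: str = "."
    query_fasta: str = "query.faa"
    out_dir: str = "run"
    reference_classes: str | None = None
    external_msa: str | None = None

    evalue_cutoff: float = 1e-5
    min_coverage: float = 0.70
    flank: int = 5
    mcl_inflation: float = 1.2
    edge_weighting: str = "neg_log_evalue"
    distance_deletion: str = "pairwise"
    rooting: str = "midpoint"  # or "outgroup:<leaf label>"
    clade_method: str = "avg_clade"
    clade_threshold: float = 0.5
    sweep_min: float = 0.05
    sweep_max: float = 1.0
    sweep_step: float = 0.05
    gcl_cutoff: float = 1.0
    gcl_comparison: str = "strict_greater"
    kmeans_k: int | None = None
    seed: int = 0

    def search_params(self) -> SearchParams:
        return SearchParams(evalue_cutoff=self.evalue_cutoff, min_coverage=self.min_coverage)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# manifest / resume machinery


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest(*parts: str) -> str:
    return hashlib.sha256("\x1f".join(parts).encode()).hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"tool": f"cognate {__version__}", "stages": {}}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except json.JSONDecodeError:
                log.warning("manifest unreadable; rebuilding")

    def stage_current(self, name: str, digest: str, outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(name)
        if not entry or entry["digest"] != digest:
            return False
        for out in outputs:
            if not out.exists() or _sha256_file(out) != entry["outputs"].get(out.name):
                return False
        return True

    def record(self, name: str, digest: str, outputs: list[Path], elapsed: float) -> None:
        self.data["stages"][name] = {
            "digest": digest,
            "outputs": {out.name: _sha256_file(out) for out in outputs},
            "seconds": round(elapsed, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=2))


# ---------------------------------------------------------------------------
# genome discovery


def load_genomes(genome_dir) -> list[GenomeTable]:
    """Load every genome in a directory: *.gff3 + *.faa pairs, or GenBank files."""
    d = Path(genome_dir)
    tables: list[GenomeTable] = []
    for gff in sorted(d.glob("*.gff3")) + sorted(d.glob("*.gff")):
        strain = gff.stem
        faa = gff.with_suffix(".faa")
        if strain == "query" or not faa.exists():
            continue
        tables.append(read_gff_fasta(gff, faa, strain_id=strain))
    for gbk in sorted(d.glob("*.gb")) + sorted(d.glob("*.gbk")) + sorted(d.glob("*.gbff")):
        tables.append(read_genbank(gbk))
    if not tables:
        raise FileNotFoundError(f"no genomes found in {genome_dir}")
    return tables


def _genome_digest(tables: list[GenomeTable]) -> str:
    h = hashlib.sha256()
    for t in sorted(tables, key=lambda t: t.strain_id):
        for g in t.genes():
            h.update(f"{g.gene_id}|{g.ordinal}|{g.protein_seq}".encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory.

    Stage outputs (in order): hits.tsv, neighborhoods.tsv, clusters.tsv,
    cluster_summary.tsv, target_cluster.faa, msa.afa, distances.tsv,
    tree.nwk, clades.tsv, sweep.tsv, gcl.tsv, gcl_summary.tsv, legend.tsv,
    annotated.nwk, kmeans.tsv and evaluation.tsv when requested, plus
    manifest.json and the resolved config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = Manifest(out / "manifest.json")

    tables = load_genomes(config.genome_dir)
    genomes_digest = _genome_digest(tables)
    gene_of = {g.gene_id: g for t in tables for g in t.genes()}
    table_of = {t.strain_id: t for t in tables}
    params = config.search_params()

    queries = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(config.query_fasta, "fasta")]
    if not queries:
        raise FileNotFoundError(f"no query sequences in {config.query_fasta}")
    query_digest = _digest(*[f"{i}:{s}" for i, s in queries])

    def stage(name: str, digest: str, outputs: list[str], fn):
        paths = [out / o for o in outputs]
        if manifest.stage_current(name, digest, paths):
            log.info("stage %s: up to date, skipped", name)
            return False
        t0 = time.time()
        try:
            fn(paths)
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest.record(name, digest, paths, time.time() - t0)
        log.info("stage %s: done in %.1fs", name, time.time() - t0)
        return True

    # -- genes ---------------------------------------------------------------
    d_genes = _digest(genomes_digest)
    stage("genes", d_genes, ["genes.tsv"], lambda p: genes_frame(tables).to_csv(p[0], sep="\t", index=False))

    # -- homolog search ------------------------------------------------------
    d_search = _digest(d_genes, query_digest, f"{config.evalue_cutoff}|{config.min_coverage}")

    def do_search(paths):
        hits = search_homologs(queries, list(gene_of.values()), params)
        if not hits:
            raise RuntimeError("homolog search found no hits")
        hits_frame(hits).to_csv(paths[0], sep="\t", index=False)

    stage("search", d_search, ["hits.tsv"], do_search)
    hits_df = pd.read_csv(out / "hits.tsv", sep="\t")
    anchors = sorted(set(hits_df["subject_id"]))

    # -- neighborhoods -------------------------------------------------------
    d_nb = _digest(d_search, str(config.flank))

    def do_neighborhoods(paths):
        nbs = [
            extract_neighborhood(table_of[gene_of[a].strain_id], a, config.flank)
            for a in anchors
        ]
        neighborhoods_frame(nbs, tables).to_csv(paths[0], sep="\t", index=False)

    stage("neighborhoods", d_nb, ["neighborhoods.tsv"], do_neighborhoods)
    nb_df = pd.read_csv(out / "neighborhoods.tsv", sep="\t")
    neighborhoods = [
        Neighborhood(
            anchor_gene_id=a,
            member_gene_ids=tuple(grp["member_gene_id"]),
            strain_id=gene_of[a].strain_id,
            flank=config.flank,
        )
        for a, grp in nb_df.groupby("anchor_gene_id", sort=True)
    ]
    nb_gene_ids = sorted(set(nb_df["member_gene_id"]))

    # -- clustering ----------------------------------------------------------
    d_clu = _digest(d_nb, f"{config.mcl_inflation}|{config.edge_weighting}")

    def do_cluster(paths):
        seqs = [(gid, gene_of[gid].protein_seq) for gid in nb_gene_ids]
        aa_hits = all_against_all(seqs, params)
        graph = build_graph(aa_hits, weighting=config.edge_weighting)
        graph.add_nodes_from(nb_gene_ids)
        assignment = assign_cluster_ids(mcl(graph, inflation=config.mcl_inflation))
        pd.DataFrame(
            sorted(assignment.membership.items()), columns=["gene_id", "cluster_id"]
        ).to_csv(paths[0], sep="\t", index=False)
        summarize_clusters(assignment, tables).to_csv(paths[1], sep="\t", index=False)

    stage("cluster", d_clu, ["clusters.tsv", "cluster_summary.tsv"], do_cluster)
    clu_df = pd.read_csv(out / "clusters.tsv", sep="\t")
    membership = dict(zip(clu_df["gene_id"], clu_df["cluster_id"]))
    sizes: dict[int, int] = clu_df["cluster_id"].value_counts().to_dict()
    clusters = ClusterAssignment(membership=membership, sizes=sizes)

    # -- target cluster ------------------------------------------------------
    anchor_cluster = int(
        pd.Series([membership[a] for a in anchors]).value_counts().idxmax()
    )
    target_leaves = [a for a in anchors if membership[a] == anchor_cluster]
    if len(target_leaves) < 2:
        raise StageError("target_cluster", RuntimeError("fewer than 2 target homologs"))
    d_target = _digest(d_clu, "target")

    def do_target(paths):
        with open(paths[0], "w") as fh:
            for gid in target_leaves:
                fh.write(f">{gid}\n{gene_of[gid].protein_seq}\n")

    stage("target_cluster", d_target, ["target_cluster.faa"], do_target)

    # -- msa / distances / tree ---------------------------------------------
    run_tree_stages(
        out_dir=out,
        manifest=manifest,
        upstream_digest=d_target,
        seqs=[(gid, gene_of[gid].protein_seq) for gid in target_leaves],
        config=config,
    )
    tree = tree_from_file(out / "tree.nwk")

    # -- clades + sweep ------------------------------------------------------
    d_clade = _digest(
        manifest.data["stages"]["tree"]["digest"],
        f"{config.clade_method}|{config.clade_threshold}|{config.sweep_min}|{config.sweep_max}|{config.sweep_step}",
    )

    def do_clades(paths):
        ca = cut_tree(tree, config.clade_method, config.clade_threshold)
        ca.to_frame().to_csv(paths[0], sep="\t", index=False)
        sweep_thresholds(
            tree, config.clade_method, config.sweep_min, config.sweep_max, config.sweep_step
        ).to_csv(paths[1], sep="\t", index=False)

    stage("clades", d_clade, ["clades.tsv", "sweep.tsv"], do_clades)
    clade_df = pd.read_csv(out / "clades.tsv", sep="\t")
    clades = CladeAssignment(
        labels=dict(zip(clade_df["leaf_id"], clade_df["clade_label"])),
        method=config.clade_method,
        threshold=config.clade_threshold,
    )

    # -- optional k-means partition of the distance matrix -------------------
    if config.kmeans_k is not None:
        from cognate.phylogeny import DistanceMatrix, kmeans_partition
        import numpy as np

        d_km = _digest(
            manifest.data["stages"]["distances"]["digest"],
            f"{config.kmeans_k}|{config.seed}",
        )

        def do_kmeans(paths):
            dist_df = pd.read_csv(out / "distances.tsv", sep="\t", index_col=0)
            dm = DistanceMatrix(labels=tuple(dist_df.index), d=np.asarray(dist_df))
            km = kmeans_partition(dm, config.kmeans_k, seed=config.seed)
            km.to_frame().to_csv(paths[0], sep="\t", index=False)

        stage("kmeans", d_km, ["kmeans.tsv"], do_kmeans)

    # -- GCL -----------------------------------------------------------------
    d_gcl = _digest(d_clade, f"{config.gcl_cutoff}|{config.gcl_comparison}")

    def do_gcl(paths):
        gene_index = {gid: gene_of[gid].strain_id for gid in gene_of}
        rows = build_gcl(
            clades,
            neighborhoods,
            clusters,
            gene_index,
            cutoff=config.gcl_cutoff,
            comparison=config.gcl_comparison,
        )
        gcl_frame(rows).to_csv(paths[0], sep="\t", index=False)
        gcl_summary_frame(rows).to_csv(paths[1], sep="\t", index=False)
        newick, legend = annotate_tree(tree, clades, rows)
        legend.to_csv(paths[2], sep="\t", index=False)
        Path(paths[3]).write_text(newick)

    stage("gcl", d_gcl, ["gcl.tsv", "gcl_summary.tsv", "legend.tsv", "annotated.nwk"], do_gcl)

    # -- evaluation ----------------------------------------------------------
    if config.reference_classes:
        ref = read_reference_classes(config.reference_classes)
        d_eval = _digest(d_clade, _digest(*[f"{k}:{v}" for k, v in sorted(ref.items())]))

        def do_eval(paths):
            result = evaluate_against_reference(clades, ref)
            result.to_frame().to_csv(paths[0], sep="\t", index=False)

        stage("evaluate", d_eval, ["evaluation.tsv"], do_eval)

    return out


def run_tree_stages(out_dir: Path, manifest: Manifest, upstream_digest: str, seqs, config: PipelineConfig) -> None:
    """MSA -> Poisson distances -> NJ tree (+rooting), with resume support."""
    import numpy as np

    from cognate.phylogeny import DistanceMatrix

    def stage(name, digest, outputs, fn):
        paths = [out_dir / o for o in outputs]
        if manifest.stage_current(name, digest, paths):
            return
        t0 = time.time()
        try:
            fn(paths)
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest.record(name, digest, paths, time.time() - t0)

    d_msa = _digest(upstream_digest, config.external_msa or "builtin")

    def do_msa(paths):
        if config.external_msa:
            rows = {r.id: str(r.seq).upper() for r in SeqIO.parse(config.external_msa, "fasta")}
            missing = [i for i, _ in seqs if i not in rows]
            if missing:
                raise ValueError(f"external MSA lacks sequences: {missing[:5]}")
            msa = Msa(rows={i: rows[i] for i, _ in seqs})
        else:
            msa = progressive_align(seqs)
        with open(paths[0], "w") as fh:
            for sid, row in msa.rows.items():
                fh.write(f">{sid}\n{row}\n")

    stage("msa", d_msa, ["msa.afa"], do_msa)
    msa = Msa(rows={r.id: str(r.seq) for r in SeqIO.parse(out_dir / "msa.afa", "fasta")})

    d_dist = _digest(d_msa, config.distance_deletion)

    def do_dist(paths):
        dm = poisson_distance_matrix(msa, deletion=config.distance_deletion)
        dm.to_frame().to_csv(paths[0], sep="\t")

    stage("distances", d_dist, ["distances.tsv"], do_dist)
    dist_df = pd.read_csv(out_dir / "distances.tsv", sep="\t", index_col=0)
    dm = DistanceMatrix(labels=tuple(dist_df.index), d=np.asarray(dist_df, dtype=float))

    d_tree = _digest(d_dist, f"nj|{config.rooting}")

    def do_tree(paths):
        unrooted = neighbor_joining(dm)
        if config.rooting == "midpoint":
            rooted = midpoint_root(unrooted)
        elif config.rooting.startswith("outgroup:"):
            label = config.rooting.split(":", 1)[1]
            taxon = unrooted.taxon_namespace.get_taxon(label)
            if taxon is None:
                raise ValueError(f"outgroup {label!r} not among leaves")
            node = unrooted.find_node_for_taxon(taxon)
            unrooted.to_outgroup_position(node, update_bipartitions=False)
            unrooted.is_rooted = True
            rooted = unrooted
        else:
            raise ValueError(f"unknown rooting {config.rooting!r}")
        Path(paths[0]).write_text(newick_write(rooted))

    stage("tree", d_tree, ["tree.nwk"], do_tree)


def run_target_sweep(config: PipelineConfig, targets: list[int]) -> list[Path]:
    """Re-run the tree/clade/GCL stages for each requested gene cluster.

    Reuses the main run's clusters.tsv (one cluster universe per run); each
    target cluster gets its own subdirectory ``target_<id>``.
    """
    out = Path(config.out_dir)
    clu_path = out / "clusters.tsv"
    if not clu_path.exists():
        raise FileNotFoundError("clusters.tsv not found; run the main pipeline first")
    clu_df = pd.read_csv(clu_path, sep="\t")
    membership = dict(zip(clu_df["gene_id"], clu_df["cluster_id"]))
    sizes = clu_df["cluster_id"].value_counts().to_dict()
    clusters = ClusterAssignment(membership=membership, sizes=sizes)
    tables = load_genomes(config.genome_dir)
    gene_of = {g.gene_id: g for t in tables for g in t.genes()}
    table_of = {t.strain_id: t for t in tables}
    nb_df = pd.read_csv(out / "neighborhoods.tsv", sep="\t")
    neighborhoods = [
        Neighborhood(
            anchor_gene_id=a,
            member_gene_ids=tuple(grp["member_gene_id"]),
            strain_id=gene_of[a].strain_id,
            flank=config.flank,
        )
        for a, grp in nb_df.groupby("anchor_gene_id", sort=True)
    ]
    results = []
    for target in targets:
        if target not in sizes:
            raise ValueError(f"unknown cluster ID {target}")
        members = sorted(g for g, c in membership.items() if c == target)
        if len(members) < 2:
            raise ValueError(f"cluster {target} has fewer than 2 sequences")
        sub_out = out / f"target_{target}"
        sub_out.mkdir(parents=True, exist_ok=True)
        manifest = Manifest(sub_out / "manifest.json")
        seqs = [(gid, gene_of[gid].protein_seq) for gid in members]
        run_tree_stages(sub_out, manifest, _digest(f"target:{target}"), seqs, config)
        tree = tree_from_file(sub_out / "tree.nwk")
        ca = cut_tree(tree, config.clade_method, config.clade_threshold)
        ca.to_frame().to_csv(sub_out / "clades.tsv", sep="\t", index=False)
        # members never hit by the query search get neighborhoods on demand;
        # genes outside the run's cluster universe cannot be counted and are
        # dropped from the pooled neighborhoods
        nb_by_anchor = {nb.anchor_gene_id: nb for nb in neighborhoods}
        for gid in members:
            if gid not in nb_by_anchor:
                table = table_of[gene_of[gid].strain_id]
                nb_by_anchor[gid] = extract_neighborhood(table, gid, config.flank)
        trimmed = [
            Neighborhood(
                anchor_gene_id=nb.anchor_gene_id,
                member_gene_ids=tuple(
                    g for g in nb.member_gene_ids if g in membership or g == nb.anchor_gene_id
                ),
                strain_id=nb.strain_id,
                flank=nb.flank,
            )
            for nb in nb_by_anchor.values()
        ]
        rows = build_gcl(
            ca,
            trimmed,
            clusters,
            {gid: gene_of[gid].strain_id for gid in gene_of},
            cutoff=config.gcl_cutoff,
            comparison=config.gcl_comparison,
        )
        gcl_frame(rows).to_csv(sub_out / "gcl.tsv", sep="\t", index=False)
        gcl_summary_frame(rows).to_csv(sub_out / "gcl_summary.tsv", sep="\t", index=False)
        results.append(sub_out)
    return results
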