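"""Seeded synthetic pangenomes with planted clades and companion gene families.

The generator emulates what the pipeline consumes from real data: a set of
annotated strains, each an ordered replicon of protein-coding genes, where a
target gene family evolves along a known strain tree and designated
"companion" families are planted at fixed gene offsets (within the ±flank
window) in designated clades.  Remaining genes are mutually unrelated random
proteins, so they fall below the homology cutoffs with overwhelming
probability.  Ground truth (true clade of every target homolog, true family
of every gene, expected conserved families per clade) is emitted alongside.

What it does not emulate: genome rearrangement, horizontal transfer, codon
structure, indels (sequences evolve by substitution only).

One global seed drives named substreams (tree / sequences / placement /
background), so each component is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from cognate.genome import GeneRecord, GenomeTable, gene_id_for

log = logging.getLogger(__name__)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TARGET_FAMILY = "target"
BACKGROUND_FAMILY = "background"


@dataclass(frozen=True)
class PlantSpec:
    """Design of one synthetic pangenome.

    ``clade_plan`` maps clade names to the strains forming each planted
    clade; strains in no clade hang off the root.  ``companion_plan`` maps a
    clade name to {family name: list of gene offsets relative to the target}
    — one planted gene copy per offset, so two offsets per family exercise
    criteria scores of 2.0 under one-anchor-per-strain clades.
    ``anchor_paralog_offset`` optionally plants a slightly diverged copy of
    each strain's target gene at that offset.  Branch lengths are in
    substitutions/site given ``mutation_rate`` = 1.
    """

    n_strains: int
    clade_plan: dict[str, tuple[str, ...]] = field(default_factory=dict)
    companion_plan: dict[str, dict[str, tuple[int, ...]]] = field(default_factory=dict)
    background_genes_per_strain: int = 24
    target_root_seq: str | None = None
    target_len: int = 180
    mutation_rate: float = 1.0
    tree_shape: float = 1.0  # Yule birth rate
    seed: int = 0
    flank: int = 5
    anchor_paralog_offset: int | None = None
    paralog_divergence: float = 0.02
    clade_height: float = 0.1
    stem_length: float = 0.45
    background_len: tuple[int, int] = (150, 400)

    def strain_ids(self) -> list[str]:
        planned = [s for strains in self.clade_plan.values() for s in strains]
        if planned:
            if len(set(planned)) != len(planned):
                raise ValueError("clade_plan assigns a strain to two clades")
            extra = self.n_strains - len(planned)
            if extra < 0:
                raise ValueError("clade_plan names more strains than n_strains")
            return planned + [f"free{i:02d}" for i in range(extra)]
        return [f"s{i:02d}" for i in range(self.n_strains)]

    def planted_offsets(self, clade: str) -> dict[int, str]:
        """offset -> family name for one clade's strains (anchor paralog included)."""
        offsets: dict[int, str] = {}
        if self.anchor_paralog_offset is not None:
            offsets[self.anchor_paralog_offset] = TARGET_FAMILY
        for fam, offs in self.companion_plan.get(clade, {}).items():
            for o in offs:
                if o == 0 or abs(o) > self.flank:
                    raise ValueError(f"offset {o} of family {fam} outside ±flank")
                if o in offsets:
                    raise ValueError(f"offset collision at {o} in clade {clade}")
                offsets[o] = fam
        return offsets

    def validate(self) -> None:
        self.strain_ids()
        if self.anchor_paralog_offset == 0:
            raise ValueError("anchor paralog offset cannot be 0")
        for clade in self.companion_plan:
            if clade not in self.clade_plan:
                raise ValueError(f"companion_plan references unknown clade {clade!r}")
            self.planted_offsets(clade)


@dataclass(frozen=True)
class GroundTruth:
    true_clade: dict[str, str]  # target-family gene_id -> clade name
    true_family: dict[str, str]  # gene_id -> family name
    expected_conserved: dict[str, frozenset[str]]  # clade -> companion family names


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def simulate_strain_tree(
    n_strains: int, birth_rate: float, seed: int | np.random.Generator
) -> dendropy.Tree:
    """A Yule (pure-birth) tree with exponential waiting times.

    Starts from the root bifurcation, so a tree with n leaves has n − 1
    internal nodes.  A final waiting period gives terminal branches nonzero
    length.  Fully deterministic under ``seed``.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    leaves: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        leaves.append(child)
    while len(leaves) < n_strains:
        wait = rng.exponential(1.0 / (birth_rate * len(leaves)))
        for lf in leaves:
            lf.edge.length += wait
        idx = int(rng.integers(len(leaves)))
        parent = leaves.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            leaves.append(child)
    wait = rng.exponential(1.0 / (birth_rate * len(leaves)))
    for lf in leaves:
        lf.edge.length += wait
    for i, lf in enumerate(leaves):
        lf.taxon = tns.require_taxon(f"s{i:02d}")
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def _scale_to_height(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    top = max(depths)
    if top > 0:
        factor = height / top
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return tree


def planted_strain_tree(spec: PlantSpec, rng: np.random.Generator) -> dendropy.Tree:
    """Strain tree with each planned clade as a monophyletic group.

    Each clade is a Yule subtree scaled to ``clade_height``, attached to the
    root by a stem of ``stem_length``; strains outside any clade hang off
    the root at the same total depth.  Without a clade plan this is a plain
    Yule tree over all strains.
    """
    strains = spec.strain_ids()
    if not spec.clade_plan:
        if spec.n_strains == 1:
            tns = dendropy.TaxonNamespace()
            root = dendropy.Node(taxon=tns.require_taxon(strains[0]))
            tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
            tree.is_rooted = True
            return tree
        tree = simulate_strain_tree(spec.n_strains, spec.tree_shape, rng)
        for leaf, strain in zip(tree.leaf_node_iter(), strains):
            leaf.taxon.label = strain
        return tree
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    for clade, members in spec.clade_plan.items():
        if len(members) == 1:
            node = dendropy.Node(taxon=tns.require_taxon(members[0]))
            node.edge.length = spec.stem_length + spec.clade_height
            root.add_child(node)
            continue
        sub = simulate_strain_tree(len(members), spec.tree_shape, rng)
        _scale_to_height(sub, spec.clade_height)
        for leaf, strain in zip(sub.leaf_node_iter(), members):
            leaf.taxon = tns.require_taxon(strain)
        sub_root = sub.seed_node
        sub_root.edge.length = spec.stem_length
        root.add_child(sub_root)
    planned = {s for members in spec.clade_plan.values() for s in members}
    for strain in strains:
        if strain in planned:
            continue
        node = dendropy.Node(taxon=tns.require_taxon(strain))
        node.edge.length = spec.stem_length + spec.clade_height
        root.add_child(node)
    if len(root.child_nodes()) == 1:
        only = root.child_nodes()[0]
        only.parent_node = None
        root = only
        root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def evolve_protein(
    tree: dendropy.Tree,
    root_seq: str,
    rate: float,
    seed: int | np.random.Generator,
) -> dict[str, str]:
    """Evolve a protein along a tree by independent per-site substitution.

    On a branch of length b each site substitutes with probability
    1 − e^(−rate·b), drawing uniformly among the other 19 residues (a
    Jukes–Cantor-style process on 20 states).  Returns leaf label -> sequence.
    """
    if not root_seq:
        raise ValueError("root sequence must be non-empty")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs: dict[dendropy.Node, np.ndarray] = {}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seq = np.array(list(root_seq))
        else:
            seq = seqs[node.parent_node].copy()
            b = node.edge.length or 0.0
            p = 1.0 - np.exp(-rate * b)
            hit = rng.random(len(seq)) < p
            if hit.any():
                current = seq[hit]
                repl = rng.choice(AMINO_ACIDS, size=int(hit.sum()))
                clash = repl == current
                while clash.any():  # redraw collisions so substitution is to another residue
                    repl[clash] = rng.choice(AMINO_ACIDS, size=int(clash.sum()))
                    clash = repl == current
                seq[hit] = repl
        seqs[node] = seq
        if node.is_leaf():
            out[node.taxon.label] = "".join(seq)
    return out


def _mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if hit.any():
        current = arr[hit]
        repl = rng.choice(AMINO_ACIDS, size=int(hit.sum()))
        clash = repl == current
        while clash.any():
            repl[clash] = rng.choice(AMINO_ACIDS, size=int(clash.sum()))
            clash = repl == current
        arr[hit] = repl
    return "".join(arr)


def build_pangenome(spec: PlantSpec) -> tuple[list[GenomeTable], GroundTruth, dendropy.Tree]:
    """Materialize the genomes described by ``spec``.

    Returns (genome tables, ground truth, the strain tree used).  Each
    strain carries one linear replicon: background genes with the target
    gene at a random interior position and planted genes at their offsets.
    """
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_tree = np.random.default_rng(streams[0])
    rng_seqs = np.random.default_rng(streams[1])
    rng_place = np.random.default_rng(streams[2])
    rng_bg = np.random.default_rng(streams[3])

    tree = planted_strain_tree(spec, rng_tree)
    root_seq = spec.target_root_seq or _random_protein(rng_seqs, spec.target_len)
    target_seqs = evolve_protein(tree, root_seq, spec.mutation_rate, rng_seqs)

    strain_clade = {
        s: clade for clade, members in spec.clade_plan.items() for s in members
    }

    # companion families evolve along the clade's subtree from their own roots
    companion_seqs: dict[str, dict[str, str]] = {}  # family -> strain -> seq
    for clade, families in spec.companion_plan.items():
        members = list(spec.clade_plan[clade])
        taxa = [t for t in tree.taxon_namespace if t.label in members]
        sub = tree.extract_tree_with_taxa(taxa=taxa)
        for fam in families:
            length = int(rng_seqs.integers(spec.background_len[0], spec.background_len[1] + 1))
            fam_root = _random_protein(rng_seqs, length)
            companion_seqs[fam] = evolve_protein(sub, fam_root, spec.mutation_rate, rng_seqs)

    tables: list[GenomeTable] = []
    true_clade: dict[str, str] = {}
    true_family: dict[str, str] = {}
    lo, hi = spec.background_len
    for strain in spec.strain_ids():
        clade = strain_clade.get(strain, "")
        offsets = spec.planted_offsets(clade) if clade else (
            {spec.anchor_paralog_offset: TARGET_FAMILY} if spec.anchor_paralog_offset else {}
        )
        span = max([0, *map(abs, offsets)])
        n_total = spec.background_genes_per_strain + 1 + len(offsets)
        margin = spec.flank + span
        if n_total < 2 * margin + 1:
            n_total = 2 * margin + 1  # keep the planted block interior
        background = [
            _random_protein(rng_bg, int(rng_bg.integers(lo, hi + 1)))
            for _ in range(n_total)
        ]
        anchor_pos = int(rng_place.integers(margin, n_total - margin))
        # assemble the ordered protein list with families
        entries: list[tuple[str, str]] = []  # (family, seq), in gene order
        bg_iter = iter(background)
        for pos in range(n_total):
            rel = pos - anchor_pos
            if rel == 0:
                entries.append((TARGET_FAMILY + ":anchor", target_seqs[strain]))
            elif rel in offsets:
                fam = offsets[rel]
                if fam == TARGET_FAMILY:
                    seq = _mutate(target_seqs[strain], spec.paralog_divergence, rng_seqs)
                    entries.append((TARGET_FAMILY + ":paralog", seq))
                else:
                    entries.append((fam, companion_seqs[fam][strain]))
            else:
                entries.append((BACKGROUND_FAMILY, next(bg_iter)))

        genes: list[GeneRecord] = []
        pos_nt = 1
        for i, (fam, seq) in enumerate(entries):
            locus = f"g{i:04d}"
            gid = gene_id_for(strain, locus)
            nt_len = 3 * len(seq) + 3
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    strain_id=strain,
                    replicon_id="chr",
                    start=pos_nt,
                    end=pos_nt + nt_len - 1,
                    strand="+" if rng_place.random() < 0.5 else "-",
                    ordinal=i,
                    protein_seq=seq,
                )
            )
            pos_nt += nt_len + int(rng_place.integers(1, 200))
            if fam.startswith(TARGET_FAMILY):
                true_family[gid] = TARGET_FAMILY
                if clade:
                    true_clade[gid] = clade
            else:
                true_family[gid] = fam
        tables.append(GenomeTable(strain_id=strain, replicons={"chr": genes}))

    expected = {
        clade: frozenset(spec.companion_plan.get(clade, {}))
        for clade in spec.clade_plan
    }
    truth = GroundTruth(
        true_clade=true_clade, true_family=true_family, expected_conserved=expected
    )
    return tables, truth, tree


def write_fixture(
    out_dir,
    tables: list[GenomeTable],
    truth: GroundTruth,
    query_seq: str,
    tree: dendropy.Tree | None = None,
) -> Path:
    """Write GFF3 + protein FASTA per strain, the query FASTA and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for table in tables:
        strain = table.strain_id
        with open(out / f"{strain}.gff3", "w") as gff, open(out / f"{strain}.faa", "w") as faa:
            gff.write("##gff-version 3\n")
            for g in table.genes():
                locus = g.gene_id.split("__", 1)[1]
                gff.write(
                    f"{g.replicon_id}\tcognate_sim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={locus}\n"
                )
                faa.write(f">{locus}\n{g.protein_seq}\n")
    with open(out / "query.faa", "w") as fh:
        fh.write(f">query_target\n{query_seq}\n")
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("gene_id\tfamily\tclade\n")
        for gid in sorted(truth.true_family):
            fh.write(f"{gid}\t{truth.true_family[gid]}\t{truth.true_clade.get(gid, '')}\n")
    if tree is not None:
        from cognate.phylogeny import newick_write

        (out / "strain_tree.nwk").write_text(newick_write(tree))
    return out


def default_e2e_spec(seed: int, n_strains: int = 20) -> PlantSpec:
    """The standard recovery fixture: 2 planted clades × 2 companion families.

    Half the strains in each clade; each companion family planted as two
    copies per strain (offsets +2,+3 / −2,−3) so its criteria score clears
    the strict >1.0 cutoff; one anchor paralog per strain at offset +1.
    """
    half = n_strains // 2
    clade_a = tuple(f"a{i:02d}" for i in range(half))
    clade_b = tuple(f"b{i:02d}" for i in range(n_strains - half))
    return PlantSpec(
        n_strains=n_strains,
        clade_plan={"cladeA": clade_a, "cladeB": clade_b},
        companion_plan={
            "cladeA": {"famA": (2, 3)},
            "cladeB": {"famB": (-2, -3)},
        },
        anchor_paralog_offset=1,
        seed=seed,
    )
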