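"""Ordered gene tables parsed from annotated genomes, and gene neighborhoods.

A genome is modeled as one or more replicons, each an ordered list of
protein-coding genes.  "Surrounding" is counted in genes (ordinal rank along
the replicon), not base pairs: the neighborhood of a homolog hit is the hit
plus up to ``flank`` genes on each side, truncated at replicon ends (or
wrapped, for replicons flagged circular).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_PROTEIN_RE = re.compile(r"^[A-Z*]+$")

STRANDS = ("+", "-")


class GenomeParseError(ValueError):
    """Raised for unusable genome annotation input."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene.

    Coordinates are 1-based inclusive (GenBank/GFF3 native).  ``ordinal`` is
    the 0-based rank of the gene along its replicon ordered by start
    coordinate (ties broken by end, then gene_id).
    """

    gene_id: str
    strain_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    ordinal: int
    protein_seq: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.protein_seq or not _PROTEIN_RE.match(self.protein_seq):
            raise ValueError(f"{self.gene_id}: protein_seq must match [A-Z*]+")


@dataclass
class GenomeTable:
    """All genes of one strain, grouped by replicon and sorted by ordinal."""

    strain_id: str
    replicons: dict[str, list[GeneRecord]]
    circular: set[str] = field(default_factory=set)
    _index: dict[str, GeneRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for rid, genes in self.replicons.items():
            for i, g in enumerate(genes):
                if g.strain_id != self.strain_id:
                    raise ValueError(
                        f"gene {g.gene_id} strain {g.strain_id} != table {self.strain_id}"
                    )
                if g.ordinal != i:
                    raise ValueError(f"replicon {rid}: ordinals not consecutive from 0")
        self._index = {g.gene_id: g for g in self.genes()}
        if len(self._index) != sum(len(v) for v in self.replicons.values()):
            raise ValueError(f"duplicate gene_id in strain {self.strain_id}")

    def genes(self):
        for genes in self.replicons.values():
            yield from genes

    def __len__(self) -> int:
        return sum(len(v) for v in self.replicons.values())

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r} in strain {self.strain_id}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index


@dataclass(frozen=True)
class Neighborhood:
    """An anchor homolog plus up to ``flank`` genes on each side, in gene order."""

    anchor_gene_id: str
    member_gene_ids: tuple[str, ...]
    strain_id: str
    flank: int = 5

    def __post_init__(self) -> None:
        if self.anchor_gene_id not in self.member_gene_ids:
            raise ValueError("anchor must be a member of its own neighborhood")
        if len(self.member_gene_ids) > 2 * self.flank + 1:
            raise ValueError("neighborhood larger than 2*flank+1")


def _assign_ordinals(genes: list[dict]) -> list[dict]:
    genes.sort(key=lambda g: (g["start"], g["end"], g["gene_id"]))
    for i, g in enumerate(genes):
        g["ordinal"] = i
    return genes


def _build_table(strain_id: str, raw: dict[str, list[dict]], circular: set[str]) -> GenomeTable:
    replicons: dict[str, list[GeneRecord]] = {}
    for rid, genes in raw.items():
        replicons[rid] = [GeneRecord(**g) for g in _assign_ordinals(genes)]
    table = GenomeTable(strain_id=strain_id, replicons=replicons, circular=circular)
    if len(table) == 0:
        raise GenomeParseError(f"no usable CDS features for strain {strain_id}")
    return table


def gene_id_for(strain_id: str, locus_tag: str) -> str:
    """Globally unique gene identifier: strain and locus tag joined by '__'."""
    return f"{strain_id}__{locus_tag}"


def read_genbank(path, strain_id: str | None = None) -> GenomeTable:
    """Parse a GenBank flat file into a :class:`GenomeTable`.

    One GeneRecord per CDS feature carrying a ``translation``; CDS without a
    translation (e.g. pseudogenes) are skipped with a warning.  Each GenBank
    record becomes one replicon; ordinals restart at 0 per replicon.  The
    strain id defaults to the first record's organism (or definition line)
    and can be overridden by the caller.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"no records in GenBank file {path}")

    if strain_id is None:
        first = records[0]
        strain_id = (
            first.annotations.get("organism") or first.description or first.id
        ).strip().replace(" ", "_")

    raw: dict[str, list[dict]] = {}
    circular: set[str] = set()
    n_skipped = 0
    for rec in records:
        if rec.annotations.get("topology") == "circular":
            circular.add(rec.id)
        genes = raw.setdefault(rec.id, [])
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            locus = (quals.get("locus_tag") or quals.get("protein_id") or [None])[0]
            translation = (quals.get("translation") or [None])[0]
            if translation is None:
                n_skipped += 1
                log.warning("CDS %s in %s lacks a translation; skipped", locus, rec.id)
                continue
            if locus is None:
                locus = f"cds{len(genes)}"
            genes.append(
                dict(
                    gene_id=gene_id_for(strain_id, locus),
                    strain_id=strain_id,
                    replicon_id=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand != -1 else "-",
                    ordinal=-1,
                    protein_seq=str(translation).upper().rstrip("*") or "X",
                )
            )
    raw = {rid: genes for rid, genes in raw.items() if genes}
    if not raw:
        raise GenomeParseError(f"no translated CDS in {path}")
    if n_skipped:
        log.info("%s: skipped %d CDS without translation", path, n_skipped)
    return _build_table(strain_id, raw, circular)


def read_gff_fasta(gff_path, faa_path, strain_id: str | None = None) -> GenomeTable:
    """Parse GFF3 CDS features plus a protein FASTA into a :class:`GenomeTable`.

    CDS feature IDs must match FASTA headers.  A CDS whose ID is absent from
    the FASTA is skipped with a warning; a duplicated protein ID is an error.
    """
    import gffutils

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(faa_path), "fasta"):
        if rec.id in seqs:
            raise GenomeParseError(f"duplicated protein ID {rec.id!r} in {faa_path}")
        seqs[rec.id] = str(rec.seq).upper()

    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise GenomeParseError(f"cannot parse GFF3 file {gff_path}: {exc}") from exc

    if strain_id is None:
        strain_id = str(gff_path).rsplit("/", 1)[-1].removesuffix(".gff3").removesuffix(".gff")

    raw: dict[str, list[dict]] = {}
    for feat in db.features_of_type("CDS"):
        cds_id = feat.attributes.get("ID", [feat.id])[0]
        if cds_id not in seqs:
            log.warning("CDS %s has no matching FASTA entry; skipped", cds_id)
            continue
        raw.setdefault(feat.seqid, []).append(
            dict(
                gene_id=gene_id_for(strain_id, cds_id),
                strain_id=strain_id,
                replicon_id=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand="-" if feat.strand == "-" else "+",
                ordinal=-1,
                protein_seq=seqs[cds_id].rstrip("*"),
            )
        )
    if not raw:
        raise GenomeParseError(f"no usable CDS in {gff_path}")
    return _build_table(strain_id, raw, set())


def extract_neighborhood(table: GenomeTable, anchor_gene_id: str, flank: int = 5) -> Neighborhood:
    """Genes with ordinal within ``flank`` of the anchor's, on the anchor's replicon.

    Membership ignores strand.  At replicon ends the window is truncated,
    unless the replicon is flagged circular and long enough, in which case
    ordinals wrap around the origin.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    anchor = table.get(anchor_gene_id)
    genes = table.replicons[anchor.replicon_id]
    n = len(genes)
    o = anchor.ordinal
    if anchor.replicon_id in table.circular and n > 2 * flank + 1:
        idx = [(o + k) % n for k in range(-flank, flank + 1)]
        members = [genes[i] for i in idx]
        members.sort(key=lambda g: g.ordinal)
    else:
        lo, hi = max(0, o - flank), min(n - 1, o + flank)
        members = genes[lo : hi + 1]
    return Neighborhood(
        anchor_gene_id=anchor_gene_id,
        member_gene_ids=tuple(g.gene_id for g in members),
        strain_id=table.strain_id,
        flank=flank,
    )


def genes_frame(tables: list[GenomeTable]) -> pd.DataFrame:
    """Flatten genome tables into the genes.tsv layout."""
    rows = [
        (g.gene_id, g.strain_id, g.replicon_id, g.start, g.end, g.strand, g.ordinal)
        for t in tables
        for g in t.genes()
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "strain_id", "replicon_id", "start", "end", "strand", "ordinal"]
    )


def neighborhoods_frame(neighborhoods: list[Neighborhood], tables: list[GenomeTable]) -> pd.DataFrame:
    """Flatten neighborhoods into the neighborhoods.tsv layout (one row per member)."""
    idx = {g.gene_id: g for t in tables for g in t.genes()}
    rows = []
    for nb in neighborhoods:
        o_anchor = idx[nb.anchor_gene_id].ordinal
        for gid in nb.member_gene_ids:
            rows.append((nb.anchor_gene_id, gid, idx[gid].ordinal - o_anchor))
    return pd.DataFrame(rows, columns=["anchor_gene_id", "member_gene_id", "offset"])
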