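"""Readers and writers for the formats the pipeline touches.

Protein FASTA and GenBank go through Bio.SeqIO; GFF3 through gffutils
(in-memory database).  Group tables, locus definitions and all result
tables are plain TSV.
"""

from __future__ import annotations

import io
import os
from collections.abc import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneRecord, Genome, GroupTable, LocusDefinition, Replicon


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Record ids are the first whitespace-delimited token of the header.
    A file whose first non-blank line is not a ``>`` header is rejected
    with the offending line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(
                f"{path}: line {lineno}: expected FASTA header starting with '>'"
            )
        break
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
            if not seq:
                fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLUMNS = 9


def read_gff3_with_fasta(gff_path: str | os.PathLike,
                         fasta_path: str | os.PathLike,
                         genome_id: str | None = None) -> Genome:
    """Build a :class:`Genome` from a GFF3 annotation plus a protein FASTA.

    CDS features must carry an ``ID`` attribute matching a FASTA record;
    replicon lengths come from ``##sequence-region`` directives.  Genes are
    sorted by (replicon, start) and ranks assigned; the GFF3 file order is
    irrelevant.
    """
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="error", keep_order=True)
    replicons: list[Replicon] = []
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            replicons.append(Replicon(parts[1], int(parts[3]),
                                      topology="circular"))
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(str(gff_path)))[0]
    proteins = dict(read_fasta(fasta_path))
    genes: list[GeneRecord] = []
    seen_seqids: list[str] = []
    missing: list[str] = []
    for feat in db.all_features():
        if feat.seqid not in seen_seqids:
            seen_seqids.append(feat.seqid)
        ftype = feat.featuretype if feat.featuretype in ("CDS", "rRNA", "tRNA") \
            else "other"
        gene_id = feat.attributes.get("ID", [None])[0] \
            or feat.attributes.get("protein_id", [None])[0]
        if gene_id is None:
            raise FormatError(f"{gff_path}: feature without ID at "
                              f"{feat.seqid}:{feat.start}")
        protein = ""
        if ftype == "CDS":
            pid = feat.attributes.get("protein_id", [gene_id])[0]
            if pid not in proteins:
                missing.append(pid)
            else:
                protein = proteins[pid]
        genes.append(GeneRecord(
            gene_id=gene_id, genome_id=genome_id, replicon_id=feat.seqid,
            start=feat.start, end=feat.end, strand=feat.strand,
            feature_type=ftype,
            product=feat.attributes.get("product", [""])[0],
            protein_seq=protein))
    if missing:
        raise FormatError(
            f"{gff_path}: CDS without matching protein in {fasta_path}: "
            f"{sorted(set(missing))}")
    if not replicons:
        # fall back to feature extent when no sequence-region directives
        extents: dict[str, int] = {}
        for g in genes:
            extents[g.replicon_id] = max(extents.get(g.replicon_id, 0), g.end)
        replicons = [Replicon(rid, extents[rid]) for rid in seen_seqids]
    genome = Genome(genome_id=genome_id, replicons=replicons, genes=genes)
    genome.assign_ranks()
    return genome


def write_gff3_with_fasta(genome: Genome, gff_path: str | os.PathLike,
                          fasta_path: str | os.PathLike,
                          source: str = "orthocore") -> None:
    """Emit the GFF3 + protein FASTA pair :func:`read_gff3_with_fasta` reads."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length}\n")
        for g in sorted(genome.genes,
                        key=lambda g: (
                            [r.replicon_id for r in genome.replicons]
                            .index(g.replicon_id), g.start)):
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([
                g.replicon_id, source, g.feature_type, str(g.start),
                str(g.end), ".", g.strand, "0" if g.feature_type == "CDS"
                else ".", attrs]) + "\n")
    write_fasta(fasta_path,
                [(g.gene_id, g.protein_seq) for g in genome.genes
                 if g.feature_type == "CDS"])


# ---------------------------------------------------------------------------
# GenBank

def read_genbank_features(path: str | os.PathLike,
                          genome_id: str | None = None) -> Genome:
    """Read one or more GenBank flat-file records into a :class:`Genome`.

    Each LOCUS becomes a replicon whose length comes from the LOCUS line;
    CDS, rRNA and tRNA features become :class:`GeneRecord` objects (CDS
    translations retained, product text kept so rRNA copies can be counted).
    """
    replicons: list[Replicon] = []
    genes: list[GeneRecord] = []
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "genbank"))
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    if genome_id is None:
        genome_id = records[0].id
    for rec in records:
        try:
            length = len(rec)
        except TypeError as exc:  # undefined sequence without length
            raise FormatError(f"{path}: record {rec.id} has no LOCUS length") \
                from exc
        if length == 0:
            raise FormatError(f"{path}: record {rec.id} has no LOCUS length")
        topology = rec.annotations.get("topology", "linear")
        replicons.append(Replicon(rec.id, length, topology=topology))
        counter = 0
        for feat in rec.features:
            if feat.type not in ("CDS", "rRNA", "tRNA"):
                continue
            counter += 1
            quals = feat.qualifiers
            gene_id = (quals.get("locus_tag") or quals.get("protein_id")
                       or [f"{rec.id}_{counter}"])[0]
            genes.append(GeneRecord(
                gene_id=gene_id, genome_id=genome_id, replicon_id=rec.id,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                feature_type=feat.type,
                product=(quals.get("product") or [""])[0],
                protein_seq=(quals.get("translation") or [""])[0]
                if feat.type == "CDS" else ""))
    genome = Genome(genome_id=genome_id, replicons=replicons, genes=genes)
    genome.assign_ranks()
    return genome


def write_genbank(genome: Genome, path: str | os.PathLike) -> None:
    """Write a minimal GenBank flat file (round-trip fixture support)."""
    records = []
    for rep in genome.replicons:
        seq = Seq("N" * rep.length)
        rec = SeqRecord(seq, id=rep.replicon_id, name=rep.replicon_id[:16],
                        description=f"{genome.genome_id} {rep.replicon_id}")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        for g in genome.genes:
            if g.replicon_id != rep.replicon_id:
                continue
            loc = SimpleLocation(g.start - 1, g.end,
                                 strand=-1 if g.strand == "-" else 1)
            quals = {"locus_tag": [g.gene_id]}
            if g.product:
                quals["product"] = [g.product]
            if g.feature_type == "CDS" and g.protein_seq:
                quals["translation"] = [g.protein_seq]
            rec.features.append(SeqFeature(loc, type=g.feature_type,
                                           qualifiers=quals))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


# ---------------------------------------------------------------------------
# Simple queries

def sequence_length(genome: Genome, replicon_id: str) -> int:
    """Length in bp of a replicon (errors on unknown replicon ids)."""
    return genome.replicon(replicon_id).length


def count_features(genome: Genome, feature_type: str,
                   product_contains: str | None = None) -> int:
    """Count features of a type, optionally filtering on product text.

    ``count_features(g, "rRNA", "16S")`` counts 16S rRNA gene copies.
    """
    n = 0
    for g in genome.genes:
        if g.feature_type != feature_type:
            continue
        if product_contains is not None and product_contains not in g.product:
            continue
        n += 1
    return n


# ---------------------------------------------------------------------------
# Group tables and locus definitions (TSV)

def read_group_table(path: str | os.PathLike,
                     reference_genome_id: str) -> GroupTable:
    """Read a two-column TSV (genome_id, group_id) into a :class:`GroupTable`."""
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: need 2 columns")
            if parts[0] == "genome_id":  # header
                continue
            groups.setdefault(parts[1], set()).add(parts[0])
    return GroupTable(groups=groups, reference_genome_id=reference_genome_id)


def write_group_table(path: str | os.PathLike, table: GroupTable) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgroup_id\n")
        for gid in sorted(table.groups):
            for genome_id in sorted(table.groups[gid]):
                fh.write(f"{genome_id}\t{gid}\n")


def read_locus_definitions(path: str | os.PathLike) -> list[LocusDefinition]:
    """Read a two-column TSV (locus_id, gene_id); gene order is file order."""
    order: list[str] = []
    loci: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: need 2 columns")
            if parts[0] == "locus_id":
                continue
            if parts[0] not in loci:
                loci[parts[0]] = []
                order.append(parts[0])
            loci[parts[0]].append(parts[1])
    return [LocusDefinition(lid, loci[lid]) for lid in order]


def write_locus_definitions(path: str | os.PathLike,
                            loci: Sequence[LocusDefinition]) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tgene_id\n")
        for locus in loci:
            for gid in locus.gene_ids:
                fh.write(f"{locus.locus_id}\t{gid}\n")
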