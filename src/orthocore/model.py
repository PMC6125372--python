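"""In-memory genome model shared by every pipeline stage.

A :class:`Genome` is a bag of :class:`GeneRecord` objects grouped by
replicon, with gene order ("rank") derived from coordinates.  Coordinates
are 1-based inclusive as in GFF3/GenBank; ranks are 0-based per replicon.
Circular replicons carry a topology flag but gene order is linearized at
the origin — downstream window and synteny operations never wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "other")


@dataclass
class GeneRecord:
    """One annotated gene.

    ``rank`` is the 0-based position in the gene order of its replicon
    (assigned by :func:`Genome.assign_ranks`, ordered by ``start``).
    ``protein_seq`` is empty for non-CDS features.
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    rank: int = -1
    feature_type: str = "CDS"
    product: str = ""
    protein_seq: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.feature_type not in FEATURE_TYPES:
            self.feature_type = "other"
        bad = set(self.protein_seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: non-amino-acid symbol(s) {sorted(bad)}"
            )


@dataclass
class Replicon:
    replicon_id: str
    length: int
    topology: str = "circular"  # or "linear"


@dataclass
class Genome:
    """An annotated genome: ordered replicons plus their genes."""

    genome_id: str
    replicons: list[Replicon] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    group_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        known = {r.replicon_id: r for r in self.replicons}
        for g in self.genes:
            if g.replicon_id not in known:
                raise ValueError(
                    f"gene {g.gene_id} on unknown replicon {g.replicon_id!r}"
                )
            rep = known[g.replicon_id]
            if rep.length and g.end > rep.length:
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds replicon "
                    f"{rep.replicon_id} length {rep.length}"
                )
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids in {self.genome_id}: {dup}")

    def assign_ranks(self) -> None:
        """Sort genes by (replicon order, start) and assign per-replicon ranks."""
        order = {r.replicon_id: i for i, r in enumerate(self.replicons)}
        self.genes.sort(key=lambda g: (order[g.replicon_id], g.start, g.gene_id))
        counters: dict[str, int] = {}
        for g in self.genes:
            g.rank = counters.get(g.replicon_id, 0)
            counters[g.replicon_id] = g.rank + 1

    @property
    def cds(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.feature_type == "CDS"]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(f"unknown replicon {replicon_id!r} in {self.genome_id}")


@dataclass
class GroupTable:
    """Assignment of genomes to phylogenetic groups, with one reference genome."""

    groups: dict[str, set[str]]
    reference_genome_id: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, members in self.groups.items():
            if not members:
                raise ValueError(f"group {gid} is empty")
            overlap = seen & members
            if overlap:
                raise ValueError(f"genomes in more than one group: {sorted(overlap)}")
            seen |= members
        if self.reference_genome_id not in seen:
            raise ValueError(
                f"reference {self.reference_genome_id!r} not in any group"
            )

    @property
    def reference_group_id(self) -> str:
        for gid, members in self.groups.items():
            if self.reference_genome_id in members:
                return gid
        raise AssertionError("unreachable")

    def group_of(self, genome_id: str) -> str:
        for gid, members in self.groups.items():
            if genome_id in members:
                return gid
        raise KeyError(genome_id)

    @property
    def genome_ids(self) -> list[str]:
        out: list[str] = []
        for gid in sorted(self.groups):
            out.extend(sorted(self.groups[gid]))
        return out


@dataclass
class LocusDefinition:
    """A named, ordered gene cluster on the reference (e.g. a flagellar system)."""

    locus_id: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"locus {self.locus_id} has no genes")
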