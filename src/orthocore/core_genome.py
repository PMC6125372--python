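"""Presence/absence over the reference gene set, group core genomes,
sharing-pattern classification and locus completeness.

Presence is family-based: a reference gene counts as present in a genome
when its ortholog family has at least one member there; copy counts are
reported alongside.  Group cores are intersections of presence columns;
sharing categories follow the three questions the comparison answers —
what is shared with other enteric groups, what is unique to the species
(the reference group), and what is unique to the reference strain itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import pandas as pd

from .model import Genome, GroupTable, LocusDefinition
from .orthology import OrthologFamily


@dataclass
class PresenceMatrix:
    """Reference genes (rank order) x genomes: boolean presence + copy counts."""

    presence: pd.DataFrame  # bool, index gene_id, columns genome_id
    counts: pd.DataFrame    # int, same shape
    reference_genome_id: str
    gene_replicons: pd.Series  # gene_id -> replicon_id on the reference

    @property
    def gene_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.columns)


@dataclass
class SharingCall:
    gene_id: str
    category: str  # group_core_shared | species_unique | strain_unique | mosaic
    per_group_presence: dict[str, str]  # group_id -> all | some | none


CATEGORIES = ("group_core_shared", "species_unique", "strain_unique", "mosaic")


def presence_matrix(families: Sequence[OrthologFamily],
                    genomes: Sequence[Genome],
                    reference: Genome) -> PresenceMatrix:
    """One row per reference CDS; presence true iff the gene's family has a
    member in the genome.  Reference genes without a family are present
    only in the reference (with their own copy count of 1)."""
    genome_ids = [g.genome_id for g in genomes]
    if reference.genome_id not in genome_ids:
        raise ValueError(
            f"reference {reference.genome_id!r} not among supplied genomes")
    fam_of: dict[str, OrthologFamily] = {}
    for fam in families:
        for gene in fam.members:
            fam_of[gene] = fam
    ref_order = {r.replicon_id: i for i, r in enumerate(reference.replicons)}
    ref_genes = sorted(reference.cds,
                       key=lambda g: (ref_order[g.replicon_id], g.rank))
    rows_presence = []
    rows_counts = []
    for g in ref_genes:
        fam = fam_of.get(g.gene_id)
        if fam is None:
            pres = [gid == reference.genome_id for gid in genome_ids]
            cnts = [1 if gid == reference.genome_id else 0
                    for gid in genome_ids]
        else:
            cnts = [fam.genome_copy_number.get(gid, 0) for gid in genome_ids]
            pres = [c > 0 for c in cnts]
        rows_presence.append(pres)
        rows_counts.append(cnts)
    index = [g.gene_id for g in ref_genes]
    return PresenceMatrix(
        presence=pd.DataFrame(rows_presence, index=index, columns=genome_ids),
        counts=pd.DataFrame(rows_counts, index=index, columns=genome_ids),
        reference_genome_id=reference.genome_id,
        gene_replicons=pd.Series({g.gene_id: g.replicon_id
                                  for g in ref_genes}))


def group_core(matrix: PresenceMatrix, groups: GroupTable,
               group_id: str) -> set[str]:
    """Reference genes present in every genome of the group."""
    if group_id not in groups.groups:
        raise KeyError(f"unknown group {group_id!r}")
    members = sorted(groups.groups[group_id])
    missing = [m for m in members if m not in matrix.presence.columns]
    if missing:
        raise ValueError(f"group {group_id} genomes absent from matrix: "
                         f"{missing}")
    sub = matrix.presence[members]
    return set(sub.index[sub.all(axis=1)])


def classify_gene(matrix_row: pd.Series, groups: GroupTable) -> SharingCall:
    """Sharing category of one presence row.

    strain_unique: present only in the reference strain.
    species_unique: present in every reference-group genome, nowhere else.
    group_core_shared: in the reference-group core and in >= 1 outside genome.
    mosaic: anything else (patchy within the reference group).
    """
    ref = groups.reference_genome_id
    ref_group = groups.reference_group_id
    per_group: dict[str, str] = {}
    for gid in sorted(groups.groups):
        members = sorted(groups.groups[gid])
        vals = [bool(matrix_row[m]) for m in members]
        per_group[gid] = "all" if all(vals) else ("some" if any(vals)
                                                  else "none")
    present = [g for g in matrix_row.index if matrix_row[g]]
    outside = [g for g in present if groups.group_of(g) != ref_group]
    if present == [ref]:
        category = "strain_unique"
    elif per_group[ref_group] == "all" and not outside:
        category = "species_unique"
    elif per_group[ref_group] == "all" and outside:
        category = "group_core_shared"
    else:
        category = "mosaic"
    return SharingCall(gene_id=str(matrix_row.name), category=category,
                       per_group_presence=per_group)


def classify_all(matrix: PresenceMatrix, groups: GroupTable,
                 ) -> list[SharingCall]:
    return [classify_gene(matrix.presence.loc[gid], groups)
            for gid in matrix.gene_ids]


def completeness_bin(fraction: float) -> str:
    """Figure-style shading bin: full (=1.0), absent (<0.10), otherwise a
    partial decile between 0.10 and 1.0."""
    if fraction >= 1.0:
        return "full"
    if fraction < 0.10:
        return "absent"
    decile = int(fraction * 10) / 10
    return f"partial_{decile:.1f}"


def locus_completeness(locus: LocusDefinition, matrix: PresenceMatrix,
                       genome_id: str) -> tuple[float, str]:
    """Fraction of the locus' genes present in ``genome_id``, plus its bin."""
    missing = [g for g in locus.gene_ids if g not in matrix.presence.index]
    if missing:
        raise KeyError(f"locus {locus.locus_id}: genes not on reference: "
                       f"{missing}")
    present = int(matrix.presence.loc[locus.gene_ids, genome_id].sum())
    fraction = present / len(locus.gene_ids)
    return fraction, completeness_bin(fraction)


def locus_completeness_table(loci: Sequence[LocusDefinition],
                             matrix: PresenceMatrix) -> pd.DataFrame:
    rows = []
    for locus in loci:
        for gid in matrix.genome_ids:
            frac, b = locus_completeness(locus, matrix, gid)
            rows.append((locus.locus_id, gid, len(locus.gene_ids),
                         round(frac, 4), b))
    return pd.DataFrame(rows, columns=["locus_id", "genome_id", "n_genes",
                                       "fraction", "bin"])


def sharing_calls_frame(calls: Sequence[SharingCall],
                        groups: GroupTable) -> pd.DataFrame:
    group_ids = sorted(groups.groups)
    rows = [(c.gene_id, c.category,
             *[c.per_group_presence[g] for g in group_ids]) for c in calls]
    return pd.DataFrame(rows, columns=["gene_id", "category",
                                       *[f"group_{g}" for g in group_ids]])


# ---------------------------------------------------------------------------
# ring-track export (the TSV stand-in for circular-map rendering)

def ring_track_export(matrix: PresenceMatrix,
                      loci: Sequence[LocusDefinition] = (),
                      conserved: dict[str, set[str]] | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-genome presence tracks along reference gene order,
    plus locus annotation rows, for external ring plotting.

    ``conserved`` optionally maps genome_id -> set of reference gene ids
    lying in a conserved (syntenic) region for that genome.
    """
    conserved = conserved or {}
    gene_ids = matrix.gene_ids
    rows = []
    for gid in matrix.genome_ids:
        cons = conserved.get(gid, set())
        col = matrix.presence[gid]
        for rank, gene in enumerate(gene_ids):
            rows.append((gid, rank, gene,
                         str(matrix.gene_replicons[gene]),
                         int(col[gene]), int(gene in cons)))
    tracks = pd.DataFrame(rows, columns=["genome_id", "ref_rank", "gene_id",
                                         "replicon_id", "present",
                                         "conserved"])
    rank_of = {g: i for i, g in enumerate(gene_ids)}
    locus_rows = [(locus.locus_id, g, rank_of[g])
                  for locus in loci for g in locus.gene_ids if g in rank_of]
    annotations = pd.DataFrame(locus_rows,
                               columns=["locus_id", "gene_id", "ref_rank"])
    return tracks, annotations


def ring_track_import(tracks: pd.DataFrame, genome_id: str) -> pd.Series:
    """Recover one genome's presence column from an exported track table."""
    sub = tracks[tracks["genome_id"] == genome_id].sort_values("ref_rank")
    return pd.Series(sub["present"].astype(bool).values,
                     index=sub["gene_id"].values, name=genome_id)
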