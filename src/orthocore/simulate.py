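"""Synthetic genome sets and expression matrices with known truth.

The generator emulates the study design the comparison pipeline is built
for: several phylogenetic groups of ~3 strains descended from common
ancestors, a universal core shared by everyone, group cores, one compact
group-unique planted cluster per definition (a species-restricted
flagellar-system analog of 55 genes and a species-restricted secretion
system of 20 genes by default), a strain-specific plasmid, strain-unique
genes, dispersed gene duplications, and per-genome block inversions.
Proteins evolve by site-independent point substitutions drawn from
background amino-acid frequencies (no indels by default), which keeps
identity and coverage analytically predictable.

Every random stream derives from the master seed by stable hashing of the
genome/group name, so adding genomes does not perturb existing ones.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io_formats import (write_gff3_with_fasta, write_group_table,
                         write_locus_definitions)
from .model import (GeneRecord, Genome, GroupTable, LocusDefinition,
                    Replicon)

# Robinson & Robinson style background amino-acid frequencies
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_FREQS = np.array([
    0.0787, 0.0151, 0.0535, 0.0668, 0.0397, 0.0696, 0.0229, 0.0590,
    0.0596, 0.0964, 0.0242, 0.0414, 0.0469, 0.0398, 0.0516, 0.0715,
    0.0558, 0.0652, 0.0110, 0.0314])
AA_FREQS = AA_FREQS / AA_FREQS.sum()

#: probability two independent background draws coincide
BACKGROUND_COLLISION = float((AA_FREQS ** 2).sum())


@dataclass
class PlantedCluster:
    locus_id: str
    size: int
    owner_group: str


@dataclass
class SimulationDesign:
    n_groups: int = 4
    strains_per_group: int = 3
    n_universal_core: int = 300
    n_group_core: int = 50
    planted_clusters: list[PlantedCluster] = field(default_factory=lambda: [
        PlantedCluster("KFS2-like", 55, "G1"),
        PlantedCluster("T6SS3-like", 20, "G1")])
    plasmid_owner: str = "G1S1"
    plasmid_genes: int = 60
    n_strain_unique: int = 10
    duplication_rate: float = 0.02
    divergence_between: float = 0.10
    divergence_within: float = 0.01
    inversions_per_genome: int = 2
    inversion_len: tuple[int, int] = (5, 30)
    protein_length_mean: int = 300
    protein_length_sd: int = 75
    protein_length_min: int = 50
    intergenic_gap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "strains_per_group", "n_universal_core",
                     "n_group_core", "plasmid_genes", "n_strain_unique",
                     "inversions_per_genome"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.divergence_between, self.divergence_within):
            if not (0.0 <= d <= 0.95):
                raise ValueError("divergence must be in [0, 0.95]")
        if not (0.0 <= self.duplication_rate <= 1.0):
            raise ValueError("duplication_rate must be in [0, 1]")
        max_cluster = max((c.size for c in self.planted_clusters), default=0)
        if max_cluster > self.n_universal_core + self.n_group_core:
            raise ValueError("planted cluster larger than the genome backbone")

    @property
    def group_ids(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_groups)]

    def strains_of(self, group_id: str) -> list[str]:
        return [f"{group_id}S{j + 1}" for j in range(self.strains_per_group)]

    @property
    def genome_ids(self) -> list[str]:
        return [s for g in self.group_ids for s in self.strains_of(g)]

    @property
    def reference_genome_id(self) -> str:
        return self.genome_ids[0]


@dataclass
class TruthSet:
    """Ground truth emitted alongside the genomes."""

    family_of: dict[str, str]            # gene_id -> family_id
    presence: pd.DataFrame               # family x genome (bool)
    locus_genes: dict[str, list[str]]    # locus_id -> reference gene ids
    duplications: list[tuple[str, str]]  # (family_id, genome_id)
    rearrangements: list[tuple[str, str, int, int]]
    # (genome_id, replicon_id, first_index, last_index) of each inversion


def _stream(seed: int, *tags) -> np.random.Generator:
    """RNG stream stably derived from the master seed and string/int tags."""
    key = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        key.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(key)


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AA), size=length, p=AA_FREQS)
    return "".join(AA[i] for i in idx)


def _protein_length(design: SimulationDesign,
                    rng: np.random.Generator) -> int:
    n = int(round(rng.normal(design.protein_length_mean,
                             design.protein_length_sd)))
    return max(design.protein_length_min, n)


def mutate_protein(seq: str, divergence: float,
                   rng: np.random.Generator) -> str:
    """Point-substitute each site with probability 1 - exp(-divergence);
    replacement residues come from background frequencies excluding the
    current residue.  Length is preserved."""
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if divergence == 0 or not seq:
        return seq
    p_sub = 1.0 - np.exp(-divergence)
    mask = rng.random(len(seq)) < p_sub
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.nonzero(mask)[0]:
        new = out[i]
        while new == out[i]:
            new = AA[rng.choice(len(AA), p=AA_FREQS)]
        out[i] = new
    return "".join(out)


def expected_identity(total_divergence: float) -> float:
    """Expected residue identity of two orthologs separated by
    ``total_divergence`` substitutions per site along their joint path:
    unchanged sites plus background collisions of changed ones."""
    e = np.exp(-total_divergence)
    return float(e + (1.0 - e) * BACKGROUND_COLLISION)


# ---------------------------------------------------------------------------
# genome-set construction

def _insert_positions(rng: np.random.Generator, n_insert: int,
                      backbone_len: int) -> list[int]:
    return sorted(int(p) for p in
                  rng.integers(0, backbone_len + 1, size=n_insert))


def simulate_genome_set(design: SimulationDesign | None = None,
                        ) -> tuple[list[Genome], GroupTable, TruthSet,
                                   list[LocusDefinition]]:
    """Generate the full genome set with its group table, planted-locus
    definitions (on the reference) and ground truth."""
    design = design or SimulationDesign()
    rng_anc = _stream(design.seed, "ancestor")

    universal = [f"u{i + 1:04d}" for i in range(design.n_universal_core)]
    anc_seq = {fam: random_protein(_protein_length(design, rng_anc), rng_anc)
               for fam in universal}
    anc_strand = {fam: "+" if rng_anc.random() < 0.5 else "-"
                  for fam in universal}

    # which universal families get a dispersed duplicate, and where
    rng_dup = _stream(design.seed, "duplications")
    n_dup = int(round(design.duplication_rate * design.n_universal_core))
    dup_fams = sorted(str(f) for f in
                      rng_dup.choice(universal, size=n_dup, replace=False))
    genome_ids = design.genome_ids
    dup_owner = {fam: genome_ids[int(rng_dup.integers(len(genome_ids)))]
                 for fam in dup_fams}

    group_payload: dict[str, dict] = {}
    for gid in design.group_ids:
        rng_g = _stream(design.seed, "group", gid)
        seqs = {fam: mutate_protein(anc_seq[fam],
                                    design.divergence_between / 2.0, rng_g)
                for fam in universal}
        core_fams = [f"{gid.lower()}c{i + 1:03d}"
                     for i in range(design.n_group_core)]
        core_seqs = {fam: random_protein(_protein_length(design, rng_g),
                                         rng_g) for fam in core_fams}
        clusters = [c for c in design.planted_clusters
                    if c.owner_group == gid]
        cluster_fams: dict[str, list[str]] = {}
        cluster_seqs: dict[str, str] = {}
        for c in clusters:
            fams = [f"{c.locus_id}_{i + 1:03d}" for i in range(c.size)]
            cluster_fams[c.locus_id] = fams
            for fam in fams:
                cluster_seqs[fam] = random_protein(
                    _protein_length(design, rng_g), rng_g)
        # group-level gene order: universal backbone + scattered group core
        # + contiguous planted clusters
        order = list(universal)
        for fam, pos in zip(core_fams,
                            _insert_positions(rng_g, len(core_fams),
                                              len(order))):
            order.insert(min(pos, len(order)), fam)
        for c in clusters:
            pos = int(rng_g.integers(0, len(order) + 1))
            order[pos:pos] = cluster_fams[c.locus_id]
        group_payload[gid] = {
            "seqs": {**seqs, **core_seqs, **cluster_seqs},
            "order": order,
            "strand": {**anc_strand,
                       **{f: "+" if rng_g.random() < 0.5 else "-"
                          for f in list(core_seqs) + list(cluster_seqs)}},
            "cluster_fams": cluster_fams,
        }

    genomes: list[Genome] = []
    family_of: dict[str, str] = {}
    presence_cols: dict[str, dict[str, bool]] = {}
    duplications: list[tuple[str, str]] = []
    rearrangements: list[tuple[str, str, int, int]] = []

    for gid in design.group_ids:
        payload = group_payload[gid]
        for sid in design.strains_of(gid):
            rng_s = _stream(design.seed, "strain", sid)
            seqs = {fam: mutate_protein(seq, design.divergence_within / 2.0,
                                        rng_s)
                    for fam, seq in sorted(payload["seqs"].items())}
            order = list(payload["order"])
            strand = dict(payload["strand"])
            uniq_fams = [f"{sid.lower()}x{i + 1:02d}"
                         for i in range(design.n_strain_unique)]
            for fam in uniq_fams:
                seqs[fam] = random_protein(_protein_length(design, rng_s),
                                           rng_s)
                strand[fam] = "+" if rng_s.random() < 0.5 else "-"
            for fam, pos in zip(uniq_fams,
                                _insert_positions(rng_s, len(uniq_fams),
                                                  len(order))):
                order.insert(min(pos, len(order)), fam)
            # dispersed exact duplicates (copied after strain mutation)
            entries = [(fam, fam) for fam in order]
            for fam in dup_fams:
                if dup_owner[fam] != sid:
                    continue
                pos = int(rng_s.integers(0, len(entries) + 1))
                entries.insert(pos, (fam + ".2", fam))
                duplications.append((fam, sid))
            # block inversions
            for _ in range(design.inversions_per_genome):
                lo, hi = design.inversion_len
                length = int(rng_s.integers(lo, hi + 1))
                if length >= len(entries):
                    continue
                start = int(rng_s.integers(0, len(entries) - length + 1))
                seg = entries[start:start + length][::-1]
                entries[start:start + length] = seg
                for label, _fam in seg:
                    cur = strand.get(label, strand.get(_fam, "+"))
                    strand[label] = "-" if cur == "+" else "+"
                rearrangements.append((sid, "chr", start, start + length - 1))

            genes: list[GeneRecord] = []
            pos_bp = 1
            for label, fam in entries:
                seq = seqs[fam]
                gene_id = f"{sid}_{label}"
                length_bp = 3 * len(seq) + 3
                start = pos_bp + design.intergenic_gap
                genes.append(GeneRecord(
                    gene_id=gene_id, genome_id=sid, replicon_id="chr",
                    start=start, end=start + length_bp - 1,
                    strand=strand.get(label, strand.get(fam, "+")),
                    feature_type="CDS", product=f"family {fam}",
                    protein_seq=seq))
                pos_bp = start + length_bp - 1
                family_of[gene_id] = fam
                presence_cols.setdefault(fam, {})[sid] = True
            replicons = [Replicon("chr", pos_bp + design.intergenic_gap,
                                  "circular")]
            # strain-specific plasmid
            if sid == design.plasmid_owner and design.plasmid_genes:
                ppos = 1
                pgenes = []
                for i in range(design.plasmid_genes):
                    fam = f"pla{i + 1:03d}"
                    seq = random_protein(_protein_length(design, rng_s),
                                         rng_s)
                    gene_id = f"{sid}_{fam}"
                    length_bp = 3 * len(seq) + 3
                    start = ppos + design.intergenic_gap
                    pgenes.append(GeneRecord(
                        gene_id=gene_id, genome_id=sid, replicon_id="pla",
                        start=start, end=start + length_bp - 1,
                        strand="+" if rng_s.random() < 0.5 else "-",
                        feature_type="CDS", product=f"plasmid family {fam}",
                        protein_seq=seq))
                    ppos = start + length_bp - 1
                    family_of[gene_id] = fam
                    presence_cols.setdefault(fam, {})[sid] = True
                replicons.append(Replicon("pla",
                                          ppos + design.intergenic_gap,
                                          "circular"))
                genes.extend(pgenes)
            genome = Genome(genome_id=sid, replicons=replicons, genes=genes,
                            group_id=gid)
            genome.assign_ranks()
            genomes.append(genome)

    presence = pd.DataFrame(
        [[bool(presence_cols.get(fam, {}).get(gid, False))
          for gid in genome_ids]
         for fam in sorted(presence_cols)],
        index=sorted(presence_cols), columns=genome_ids)
    groups = GroupTable(
        groups={gid: set(design.strains_of(gid)) for gid in design.group_ids},
        reference_genome_id=design.reference_genome_id)
    ref = design.reference_genome_id
    ref_group = groups.reference_group_id
    locus_genes = {
        locus_id: [f"{ref}_{fam}" for fam in fams]
        for locus_id, fams in
        group_payload[ref_group]["cluster_fams"].items()}
    loci = [LocusDefinition(lid, genes)
            for lid, genes in locus_genes.items()]
    truth = TruthSet(family_of=family_of, presence=presence,
                     locus_genes=locus_genes, duplications=duplications,
                     rearrangements=rearrangements)
    return genomes, groups, truth, loci


def write_genome_set(design: SimulationDesign, outdir: str | os.PathLike,
                     ) -> tuple[list[Genome], GroupTable, TruthSet,
                                list[LocusDefinition]]:
    """Emit the GFF3 + protein FASTA + group TSV + locus TSV + truth TSVs
    the pipeline consumes; returns the in-memory objects as well."""
    genomes, groups, truth, loci = simulate_genome_set(design)
    os.makedirs(outdir, exist_ok=True)
    for genome in genomes:
        write_gff3_with_fasta(
            genome, os.path.join(outdir, f"{genome.genome_id}.gff3"),
            os.path.join(outdir, f"{genome.genome_id}.faa"))
    write_group_table(os.path.join(outdir, "groups.tsv"), groups)
    write_locus_definitions(os.path.join(outdir, "loci.tsv"), loci)
    pd.Series(truth.family_of, name="family_id").rename_axis("gene_id") \
        .to_frame().to_csv(os.path.join(outdir, "truth_families.tsv"),
                           sep="\t")
    truth.presence.astype(int).rename_axis("family_id") \
        .to_csv(os.path.join(outdir, "truth_presence.tsv"), sep="\t")
    pd.DataFrame(truth.duplications, columns=["family_id", "genome_id"]) \
        .to_csv(os.path.join(outdir, "truth_duplications.tsv"), sep="\t",
                index=False)
    pd.DataFrame(truth.rearrangements,
                 columns=["genome_id", "replicon_id", "first_index",
                          "last_index"]) \
        .to_csv(os.path.join(outdir, "truth_rearrangements.tsv"), sep="\t",
                index=False)
    return genomes, groups, truth, loci


# ---------------------------------------------------------------------------
# expression

def simulate_expression(n_genes: int = 2000,
                        planted_block: range | list[int] = (),
                        effect_fc: float = 4.0, cv: float = 0.1,
                        n_reps: int = 4, seed: int = 0,
                        gene_ids: list[str] | None = None,
                        baseline_mean: float = 1000.0,
                        baseline_sigma: float = 1.0) -> ExpressionMatrix:
    """Log-normal two-condition intensities with one up-regulated block.

    Gene baselines are log-normal around ``baseline_mean``; replicate noise
    is log-normal with coefficient of variation ``cv``; treatment means are
    multiplied by ``effect_fc`` at the ranks in ``planted_block``.
    """
    rng = _stream(seed, "expression")
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    block = set(int(i) for i in planted_block)
    if block and (min(block) < 0 or max(block) >= n_genes):
        raise ValueError("planted_block ranks outside gene range")
    base = baseline_mean * np.exp(
        rng.normal(0.0, baseline_sigma, size=n_genes)
        - baseline_sigma ** 2 / 2)
    sigma = np.sqrt(np.log1p(cv ** 2))
    fc = np.ones(n_genes)
    fc[list(block)] = effect_fc
    samples = [f"T{i + 1}" for i in range(n_reps)] + \
              [f"C{i + 1}" for i in range(n_reps)]
    cols = {}
    for s in samples:
        mean = base * fc if s.startswith("T") else base
        noise = np.exp(rng.normal(0.0, sigma, size=n_genes)
                       - sigma ** 2 / 2)
        cols[s] = mean * noise
    values = pd.DataFrame(cols, index=gene_ids)
    conditions = {s: "treatment" if s.startswith("T") else "control"
                  for s in samples}
    return ExpressionMatrix(values=values, conditions=conditions)
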