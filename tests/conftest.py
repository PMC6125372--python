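from __future__ import annotations

import pytest

from orthocore.model import GeneRecord, Genome, GroupTable, Replicon
from orthocore.pipeline import compare_genomes
from orthocore.simulate import (PlantedCluster, SimulationDesign,
                                simulate_genome_set)


def make_genome(genome_id: str, gene_ids: list[str],
                proteins: dict[str, str] | None = None,
                replicon_id: str = "chr") -> Genome:
    """A minimal single-replicon genome with genes in the given order."""
    proteins = proteins or {}
    genes = []
    pos = 1
    for gid in gene_ids:
        seq = proteins.get(gid, "M")
        length = 3 * len(seq) + 3
        genes.append(GeneRecord(
            gene_id=gid, genome_id=genome_id, replicon_id=replicon_id,
            start=pos, end=pos + length - 1, strand="+",
            feature_type="CDS", protein_seq=seq))
        pos += length + 10
    genome = Genome(genome_id=genome_id,
                    replicons=[Replicon(replicon_id, pos + 100, "linear")],
                    genes=genes)
    genome.assign_ranks()
    return genome


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down genome set that keeps every structural feature of the
    default study design but runs in seconds."""
    return SimulationDesign(
        n_groups=2, strains_per_group=2, n_universal_core=40,
        n_group_core=8,
        planted_clusters=[PlantedCluster("mini-cluster", 6, "G1")],
        plasmid_owner="G1S1", plasmid_genes=8, n_strain_unique=3,
        duplication_rate=0.05, inversions_per_genome=1,
        inversion_len=(3, 6), protein_length_mean=120,
        protein_length_sd=20, protein_length_min=50, seed=7)


@pytest.fixture(scope="session")
def small_genome_set(small_design):
    return simulate_genome_set(small_design)


@pytest.fixture(scope="session")
def small_compare(small_genome_set):
    genomes, groups, truth, loci = small_genome_set
    result = compare_genomes(genomes, groups, loci)
    return result, truth


@pytest.fixture(scope="session")
def default_design():
    """The full study-design analog: 4 groups x 3 strains, 300 universal
    core families, planted 55- and 20-gene group-unique clusters, plasmid,
    divergence 0.10 between / 0.01 within groups."""
    return SimulationDesign(seed=1)


@pytest.fixture(scope="session")
def default_genome_set(default_design):
    return simulate_genome_set(default_design)


@pytest.fixture(scope="session")
def default_compare(default_genome_set):
    """Full comparison pipeline on the default design (minutes)."""
    genomes, groups, truth, loci = default_genome_set
    result = compare_genomes(genomes, groups, loci)
    return result, truth, loci
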