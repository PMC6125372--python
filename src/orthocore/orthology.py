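"""All-vs-all protein comparison, hit filtering, reciprocal best hits and
ortholog families.

The comparison is an exact Smith–Waterman local alignment with affine gap
penalties (Bio.Align.PairwiseAligner) under BLOSUM62, replacing the seed
heuristic of BLASTp: at desk scale the thresholds, not the search
heuristic, define the procedure.  A gap of length L costs
``gap_open + L * gap_extend``.  E-values follow Karlin–Altschul statistics
with the published gapped BLOSUM62 constants (lambda = 0.267, K = 0.041)
over the search space m*n of the two sequence lengths.

Hits are kept when identity >= 35%, coverage >= 60% and E <= 1e-5
(inclusive boundaries).  Orthologs are reciprocal best bitscore hits per
genome pair; families are connected components of the RBH graph, with
edge-less genes recruited to the family of their best filtered hit so that
in-paralogs surface as copy number >= 2.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from collections.abc import Callable, Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .model import AA_ALPHABET, Genome

LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041
LN2 = math.log(2.0)


@dataclass
class OrthologyThresholds:
    """Hit-filtering thresholds and alignment parameters.

    ``coverage_on`` selects which coverage the 60% rule applies to:
    ``"both"`` (min of query and subject coverage — the strictest symmetric
    reading), ``"query"`` or ``"subject"``.  The k-mer prefilter skips
    exact alignment of sequence pairs sharing fewer than
    ``min_shared_kmers`` distinct k-mers; such pairs cannot realistically
    reach 35% identity at 60% coverage.
    """

    min_identity: float = 0.35
    min_coverage: float = 0.60
    max_evalue: float = 1e-5
    substitution_matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    coverage_on: str = "both"
    prefilter: bool = True
    kmer_size: int = 5
    min_shared_kmers: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0, 1]")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in [0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.coverage_on not in ("both", "query", "subject"):
            raise ValueError("coverage_on must be both/query/subject")


@dataclass
class AlignmentHit:
    query_gene: str
    subject_gene: str
    raw_score: int
    bitscore: float
    evalue: float
    identity: float
    coverage_query: float
    coverage_subject: float
    aln_length: int

    def swapped(self) -> "AlignmentHit":
        """The same alignment viewed from the subject's side."""
        return AlignmentHit(
            query_gene=self.subject_gene, subject_gene=self.query_gene,
            raw_score=self.raw_score, bitscore=self.bitscore,
            evalue=self.evalue, identity=self.identity,
            coverage_query=self.coverage_subject,
            coverage_subject=self.coverage_query,
            aln_length=self.aln_length)


@dataclass
class RBHPair:
    """An unordered reciprocal-best-hit ortholog pair between two genomes."""

    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str
    bitscore: float
    in_conserved_region: bool = False

    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class OrthologFamily:
    family_id: str
    members: set[str] = field(default_factory=set)
    genome_copy_number: dict[str, int] = field(default_factory=dict)


def _aligner(thresholds: OrthologyThresholds) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        thresholds.substitution_matrix_name)
    # first gap residue costs open+extend so a length-L gap costs open+L*extend
    aligner.open_gap_score = -(thresholds.gap_open + thresholds.gap_extend)
    aligner.extend_gap_score = -thresholds.gap_extend
    return aligner


def _check_alphabet(seq: str, label: str) -> None:
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{label}: residue(s) outside amino-acid alphabet: "
                         f"{sorted(bad)}")


def bitscore_from_raw(raw_score: float, lam: float = LAMBDA_GAPPED,
                      k: float = K_GAPPED) -> float:
    """Normalized score in bits: (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(k)) / LN2


def evalue_from_bitscore(bitscore: float, m_residues: int,
                         n_residues: int) -> float:
    """Expected chance hits in an m x n search space: E = m*n*2^-bits."""
    if m_residues < 1 or n_residues < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return float(m_residues) * float(n_residues) * 2.0 ** (-bitscore)


def align_local(seq_a: str, seq_b: str,
                thresholds: OrthologyThresholds | None = None,
                query_id: str = "query", subject_id: str = "subject",
                _aligner_obj: Align.PairwiseAligner | None = None,
                ) -> AlignmentHit | None:
    """Optimal local alignment of two proteins, or None if no positive score.

    Identity is the fraction of alignment columns (gap columns included)
    with identical residues; coverages are aligned residues over sequence
    length.  The E-value uses the two sequence lengths as search space.
    """
    thresholds = thresholds or OrthologyThresholds()
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequence")
    _check_alphabet(seq_a, query_id)
    _check_alphabet(seq_b, subject_id)
    aligner = _aligner_obj or _aligner(thresholds)
    alignments = aligner.align(seq_a, seq_b)
    if alignments.score <= 0:
        return None
    alignment = alignments[0]
    score = alignment.score
    counts = alignment.counts()
    identities = counts.identities
    acols = alignment.length
    coords = alignment.coordinates
    qcols = int(coords[0][-1] - coords[0][0])
    scols = int(abs(coords[1][-1] - coords[1][0]))
    bit = bitscore_from_raw(score)
    return AlignmentHit(
        query_gene=query_id, subject_gene=subject_id,
        raw_score=int(round(score)), bitscore=bit,
        evalue=evalue_from_bitscore(bit, len(seq_a), len(seq_b)),
        identity=identities / acols if acols else 0.0,
        coverage_query=qcols / len(seq_a),
        coverage_subject=scols / len(seq_b),
        aln_length=acols)


def hit_passes(hit: AlignmentHit, thresholds: OrthologyThresholds) -> bool:
    if thresholds.coverage_on == "query":
        cov = hit.coverage_query
    elif thresholds.coverage_on == "subject":
        cov = hit.coverage_subject
    else:
        cov = min(hit.coverage_query, hit.coverage_subject)
    return (hit.identity >= thresholds.min_identity
            and cov >= thresholds.min_coverage
            and hit.evalue <= thresholds.max_evalue)


def filter_hits(hits: Iterable[AlignmentHit],
                thresholds: OrthologyThresholds | None = None,
                ) -> list[AlignmentHit]:
    """Keep hits meeting the identity / coverage / E-value thresholds
    (boundary values retained)."""
    thresholds = thresholds or OrthologyThresholds()
    return [h for h in hits if hit_passes(h, thresholds)]


# ---------------------------------------------------------------------------
# all-vs-all with k-mer prefilter

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def candidate_pairs(genome_a: Genome, genome_b: Genome,
                    thresholds: OrthologyThresholds) -> list[tuple[str, str]]:
    """Gene pairs worth aligning: all pairs, or pairs sharing enough k-mers."""
    cds_a = [g for g in genome_a.cds if g.protein_seq]
    cds_b = [g for g in genome_b.cds if g.protein_seq]
    if not thresholds.prefilter:
        return [(a.gene_id, b.gene_id) for a in cds_a for b in cds_b]
    k = thresholds.kmer_size
    index: dict[str, list[str]] = defaultdict(list)
    for b in cds_b:
        for kmer in _kmer_set(b.protein_seq, k):
            index[kmer].append(b.gene_id)
    pairs: list[tuple[str, str]] = []
    for a in cds_a:
        shared: Counter[str] = Counter()
        for kmer in _kmer_set(a.protein_seq, k):
            for bid in index.get(kmer, ()):
                shared[bid] += 1
        for bid in sorted(bid for bid, n in shared.items()
                          if n >= thresholds.min_shared_kmers):
            pairs.append((a.gene_id, bid))
    return pairs


def genome_pair_hits(genome_a: Genome, genome_b: Genome,
                     thresholds: OrthologyThresholds | None = None,
                     filtered: bool = True) -> list[AlignmentHit]:
    """Align candidate gene pairs between two genomes; return directional
    hits for both directions (a->b and b->a)."""
    thresholds = thresholds or OrthologyThresholds()
    aligner = _aligner(thresholds)
    seq_a = {g.gene_id: g.protein_seq for g in genome_a.cds if g.protein_seq}
    seq_b = {g.gene_id: g.protein_seq for g in genome_b.cds if g.protein_seq}
    hits: list[AlignmentHit] = []
    for aid, bid in candidate_pairs(genome_a, genome_b, thresholds):
        sa, sb = seq_a[aid], seq_b[bid]
        if filtered:
            # a raw score below this cannot reach the E-value threshold,
            # so the traceback can be skipped without changing the output
            bits_needed = math.log2(len(sa) * len(sb)
                                    / thresholds.max_evalue)
            min_raw = (bits_needed * LN2 + math.log(K_GAPPED)) / LAMBDA_GAPPED
            if aligner.score(sa, sb) < min_raw:
                continue
        hit = align_local(sa, sb, thresholds,
                          query_id=aid, subject_id=bid, _aligner_obj=aligner)
        if hit is None:
            continue
        if filtered and not hit_passes(hit, thresholds):
            continue
        hits.append(hit)
        hits.append(hit.swapped())
    return hits


# ---------------------------------------------------------------------------
# reciprocal best hits

def _best_subject(candidates: list[AlignmentHit],
                  rank_of: dict[str, int],
                  prefer: Callable[[str, str], bool] | None = None,
                  tie_margin: float = 0.0) -> str:
    """Deterministic best partner: max bitscore, ties broken by synteny
    preference (when given), then higher identity, then lower partner rank."""
    best_bits = max(c.bitscore for c in candidates)
    tied = [c for c in candidates if c.bitscore >= best_bits - tie_margin]
    if prefer is not None and len(tied) > 1:
        preferred = [c for c in tied
                     if prefer(c.query_gene, c.subject_gene)]
        if preferred:
            tied = preferred
    tied.sort(key=lambda c: (-c.bitscore, -c.identity,
                             rank_of.get(c.subject_gene, 1 << 30),
                             c.subject_gene))
    return tied[0].subject_gene


def reciprocal_best_hits(genome_a: Genome, genome_b: Genome,
                         filtered_hits: Sequence[AlignmentHit],
                         prefer: Callable[[str, str], bool] | None = None,
                         tie_margin: float = 0.0) -> list[RBHPair]:
    """RBH pairs for one genome pair: (a, b) is a pair iff b is a's best
    subject in B and a is b's best subject in A (bitscore ranking;
    deterministic tie-breaking).

    ``prefer(query, subject)`` optionally promotes tied candidates lying in
    a conserved (syntenic) region; see the synteny module.
    """
    genes_a = {g.gene_id for g in genome_a.cds}
    genes_b = {g.gene_id for g in genome_b.cds}
    rank_of = {g.gene_id: g.rank for g in genome_a.genes + genome_b.genes}
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in filtered_hits:
        if h.query_gene in genes_a and h.subject_gene in genes_b:
            by_query[h.query_gene].append(h)
        elif h.query_gene in genes_b and h.subject_gene in genes_a:
            by_query[h.query_gene].append(h)
    best: dict[str, str] = {}
    for q in sorted(by_query):
        best[q] = _best_subject(by_query[q], rank_of, prefer, tie_margin)
    pairs: list[RBHPair] = []
    seen: set[frozenset] = set()
    for a in sorted(genes_a):
        b = best.get(a)
        if b is None or best.get(b) != a:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        bits = max(h.bitscore for h in by_query[a] if h.subject_gene == b)
        pairs.append(RBHPair(gene_a=a, gene_b=b,
                             genome_a=genome_a.genome_id,
                             genome_b=genome_b.genome_id, bitscore=bits))
    return pairs


# ---------------------------------------------------------------------------
# families

def build_families(all_rbh_pairs: Sequence[RBHPair],
                   gene_genomes: dict[str, str],
                   hits: Sequence[AlignmentHit] | None = None,
                   include_singletons: bool = False) -> list[OrthologFamily]:
    """Ortholog families as connected components of the RBH graph.

    ``gene_genomes`` maps every gene id to its genome (used for copy
    numbers).  When filtered ``hits`` are supplied, genes without any RBH
    edge are recruited into the family of their best-bitscore hit partner —
    this is how in-paralogs (duplicates that lost every reciprocal tie)
    surface as copy number >= 2.  ``include_singletons`` additionally emits
    one-gene families for genes left without a family.
    """
    graph = nx.Graph()
    for p in all_rbh_pairs:
        graph.add_edge(p.gene_a, p.gene_b)
    components = [set(c) for c in nx.connected_components(graph)]
    assigned: dict[str, int] = {}
    for i, comp in enumerate(components):
        for g in comp:
            assigned[g] = i
    if hits is not None:
        best_partner: dict[str, tuple[float, str]] = {}
        for h in hits:
            if h.query_gene in assigned:
                continue
            cur = best_partner.get(h.query_gene)
            cand = (h.bitscore, h.subject_gene)
            if cur is None or cand[0] > cur[0] or \
                    (cand[0] == cur[0] and cand[1] < cur[1]):
                best_partner[h.query_gene] = cand
        for gene in sorted(best_partner):
            _, partner = best_partner[gene]
            if partner in assigned:
                components[assigned[partner]].add(gene)
    if include_singletons:
        in_family = set().union(*components) if components else set()
        for gene in sorted(gene_genomes):
            if gene not in in_family:
                components.append({gene})
    components.sort(key=lambda c: sorted(c)[0])
    families: list[OrthologFamily] = []
    for i, comp in enumerate(components):
        copy_number: dict[str, int] = {}
        for g in comp:
            genome = gene_genomes[g]
            copy_number[genome] = copy_number.get(genome, 0) + 1
        families.append(OrthologFamily(
            family_id=f"F{i + 1:05d}", members=comp,
            genome_copy_number=copy_number))
    return families


def copy_number_table(families: Sequence[OrthologFamily],
                      genomes: Sequence[Genome]) -> pd.DataFrame:
    """Family x genome integer copy counts (0 for absence)."""
    genome_ids = [g.genome_id for g in genomes]
    data = {fam.family_id: [fam.genome_copy_number.get(gid, 0)
                            for gid in genome_ids]
            for fam in families}
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=genome_ids).astype(int)


# ---------------------------------------------------------------------------
# TSV export

def write_hits_tsv(path, hits: Iterable[AlignmentHit]) -> None:
    cols = ["query", "subject", "raw_score", "bitscore", "evalue",
            "identity", "cov_q", "cov_s"]
    rows = [(h.query_gene, h.subject_gene, h.raw_score,
             round(h.bitscore, 3), f"{h.evalue:.3e}",
             round(h.identity, 4), round(h.coverage_query, 4),
             round(h.coverage_subject, 4)) for h in hits]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_rbh_tsv(path, pairs: Iterable[RBHPair]) -> None:
    cols = ["gene_a", "gene_b", "genome_a", "genome_b", "bitscore",
            "in_conserved_region"]
    rows = [(p.gene_a, p.gene_b, p.genome_a, p.genome_b,
             round(p.bitscore, 3), int(p.in_conserved_region))
            for p in pairs]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_family_tsv(path, families: Sequence[OrthologFamily],
                     gene_genomes: dict[str, str]) -> None:
    rows = []
    for fam in families:
        for gene in sorted(fam.members):
            rows.append((fam.family_id, gene_genomes[gene], gene))
    pd.DataFrame(rows, columns=["family_id", "genome_id", "gene_id"]) \
        .to_csv(path, sep="\t", index=False)
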