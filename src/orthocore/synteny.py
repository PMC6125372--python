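"""Collinear conserved regions between the reference and another genome.

Conserved regions enter the pipeline only as a binary "lies in a
conserved region" attribute used to weight ortholog assignments.  A
nucleotide-level whole-genome aligner could supply that attribute; here
it comes from gene-order collinearity, which preserves the same role
while staying self-contained: maximal runs of RBH pairs whose ranks
advance monotonically (same or inverted orientation) on both genomes,
tolerating a bounded number of unmatched intervening genes on either
side.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import pandas as pd

from .model import Genome
from .orthology import AlignmentHit, RBHPair, reciprocal_best_hits


@dataclass
class SyntenyConfig:
    """``min_block_len`` genes per block; ``max_gap`` unmatched genes
    tolerated between consecutive block members on either genome;
    ``tie_margin`` bits within which competing hits count as tied when
    conserved-region weighting resolves ambiguous assignments."""

    min_block_len: int = 3
    max_gap: int = 2
    tie_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.min_block_len < 2:
            raise ValueError("min_block_len must be >= 2")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.tie_margin < 0:
            raise ValueError("tie_margin must be >= 0")


@dataclass
class SyntenyBlock:
    genome_pair: tuple[str, str]
    replicon_pair: tuple[str, str]
    pairs: list[RBHPair]
    orientation: str  # "same" | "inverted"
    ref_rank_span: tuple[int, int]
    other_rank_span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.pairs)


def _anchors(ref_genome: Genome, other_genome: Genome,
             rbh_pairs: Sequence[RBHPair]):
    """RBH pairs as (ref_replicon, ref_rank, other_replicon, other_rank, pair),
    sorted along the reference."""
    ref_pos = {g.gene_id: (g.replicon_id, g.rank) for g in ref_genome.genes}
    oth_pos = {g.gene_id: (g.replicon_id, g.rank) for g in other_genome.genes}
    ref_order = {r.replicon_id: i for i, r in enumerate(ref_genome.replicons)}
    anchors = []
    for p in rbh_pairs:
        if p.gene_a in ref_pos and p.gene_b in oth_pos:
            rg, og = p.gene_a, p.gene_b
        elif p.gene_b in ref_pos and p.gene_a in oth_pos:
            rg, og = p.gene_b, p.gene_a
        else:
            continue
        rrep, rrank = ref_pos[rg]
        orep, orank = oth_pos[og]
        anchors.append((rrep, rrank, orep, orank, p))
    anchors.sort(key=lambda a: (ref_order.get(a[0], 1 << 30), a[1]))
    return anchors


def _step_ok(prev, cur, direction: int, max_gap: int) -> bool:
    """Can ``cur`` extend a run ending at ``prev`` in ``direction``
    (+1 same, -1 inverted, 0 undetermined)?  Both anchors must share the
    replicon pair and leave at most ``max_gap`` unmatched genes between
    them on each genome."""
    if prev[0] != cur[0] or prev[2] != cur[2]:
        return False
    ref_gap = cur[1] - prev[1] - 1
    if ref_gap > max_gap:
        return False
    delta = cur[3] - prev[3]
    if delta == 0:
        return False
    if direction == 0:
        return abs(delta) - 1 <= max_gap
    return delta * direction > 0 and abs(delta) - 1 <= max_gap


def detect_blocks(ref_genome: Genome, other_genome: Genome,
                  rbh_pairs: Sequence[RBHPair],
                  config: SyntenyConfig | None = None) -> list[SyntenyBlock]:
    """Greedy left-to-right partition of reference-ordered RBH anchors into
    maximal collinear runs; runs shorter than ``min_block_len`` are
    dropped.  Blocks never overlap on the reference."""
    config = config or SyntenyConfig()
    anchors = _anchors(ref_genome, other_genome, rbh_pairs)
    blocks: list[SyntenyBlock] = []
    run: list = []
    direction = 0

    def flush() -> None:
        nonlocal run, direction
        if len(run) >= config.min_block_len:
            ref_ranks = [a[1] for a in run]
            oth_ranks = [a[3] for a in run]
            blocks.append(SyntenyBlock(
                genome_pair=(ref_genome.genome_id, other_genome.genome_id),
                replicon_pair=(run[0][0], run[0][2]),
                pairs=[a[4] for a in run],
                orientation="same" if direction >= 0 else "inverted",
                ref_rank_span=(min(ref_ranks), max(ref_ranks)),
                other_rank_span=(min(oth_ranks), max(oth_ranks))))
        run = []
        direction = 0

    for anchor in anchors:
        if not run:
            run = [anchor]
            continue
        if _step_ok(run[-1], anchor, direction, config.max_gap):
            if direction == 0:
                direction = 1 if anchor[3] > run[-1][3] else -1
            run.append(anchor)
        else:
            flush()
            run = [anchor]
    flush()
    return blocks


def mark_conserved(rbh_pairs: Sequence[RBHPair],
                   blocks: Sequence[SyntenyBlock]) -> list[RBHPair]:
    """Set ``in_conserved_region`` on each pair: true iff it belongs to a
    detected block."""
    member_keys = {p.key() for b in blocks for p in b.pairs}
    for pair in rbh_pairs:
        pair.in_conserved_region = pair.key() in member_keys
    return list(rbh_pairs)


def _span_preference(ref_genome: Genome, other_genome: Genome,
                     blocks: Sequence[SyntenyBlock],
                     max_gap: int = 2):
    """prefer(query, subject) -> True when the candidate pair is collinear
    with some block: its anchor, inserted at the candidate's reference
    rank, must satisfy the block's step constraints against the
    neighboring anchors (any existing anchor at the same reference rank is
    replaced, so re-resolution of a current pairing stays preferred)."""
    pos = {g.gene_id: (g.genome_id, g.replicon_id, g.rank)
           for g in ref_genome.genes + other_genome.genes}
    ref_pos = {g.gene_id: (g.replicon_id, g.rank)
               for g in ref_genome.genes}
    oth_pos = {g.gene_id: (g.replicon_id, g.rank)
               for g in other_genome.genes}
    prepared = []
    for b in blocks:
        anchors = []
        for p in b.pairs:
            rg = p.gene_a if p.gene_a in ref_pos else p.gene_b
            og = p.gene_b if rg == p.gene_a else p.gene_a
            anchors.append((ref_pos[rg][1], oth_pos[og][1]))
        anchors.sort()
        direction = 1 if b.orientation == "same" else -1
        prepared.append((b.replicon_pair, anchors, direction))

    def _fits(anchors, direction, ref_rank, oth_rank) -> bool:
        neighbors = [a for a in anchors if a[0] != ref_rank]
        pred = max((a for a in neighbors if a[0] < ref_rank), default=None)
        succ = min((a for a in neighbors if a[0] > ref_rank), default=None)
        if pred is None and succ is None:
            return False
        if pred is not None:
            if ref_rank - pred[0] - 1 > max_gap:
                return False
            delta = (oth_rank - pred[1]) * direction
            if delta < 1 or delta - 1 > max_gap:
                return False
        if succ is not None:
            if succ[0] - ref_rank - 1 > max_gap:
                return False
            delta = (succ[1] - oth_rank) * direction
            if delta < 1 or delta - 1 > max_gap:
                return False
        return True

    def prefer(query: str, subject: str) -> bool:
        if query not in pos or subject not in pos:
            return False
        qg, qrep, qrank = pos[query]
        if qg == ref_genome.genome_id:
            ref_rep, ref_rank = qrep, qrank
            oth_rep, oth_rank = pos[subject][1], pos[subject][2]
        else:
            oth_rep, oth_rank = qrep, qrank
            ref_rep, ref_rank = pos[subject][1], pos[subject][2]
        for replicon_pair, anchors, direction in prepared:
            if replicon_pair != (ref_rep, oth_rep):
                continue
            if not anchors:
                continue
            if not (anchors[0][0] - max_gap - 1 <= ref_rank
                    <= anchors[-1][0] + max_gap + 1):
                continue
            if _fits(anchors, direction, ref_rank, oth_rank):
                return True
        return False

    return prefer


def resolve_ambiguous(hits: Sequence[AlignmentHit],
                      rbh_pairs: Sequence[RBHPair],
                      ref_genome: Genome, other_genome: Genome,
                      config: SyntenyConfig | None = None) -> list[RBHPair]:
    """Re-derive RBH pairs weighting tied candidates by conserved-region
    affiliation.

    Blocks detected from the current pairs define conserved spans; where a
    gene has several best hits within ``tie_margin`` bits, a candidate
    inside a span beats one outside.  Remaining ties fall back to the
    orthology tie-breaking (identity, then rank).  With no ties the output
    equals the input pairing.
    """
    config = config or SyntenyConfig()
    blocks = detect_blocks(ref_genome, other_genome, rbh_pairs, config)
    prefer = _span_preference(ref_genome, other_genome, blocks,
                              config.max_gap)
    resolved = reciprocal_best_hits(ref_genome, other_genome, hits,
                                    prefer=prefer,
                                    tie_margin=config.tie_margin)
    blocks2 = detect_blocks(ref_genome, other_genome, resolved, config)
    return mark_conserved(resolved, blocks2)


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = [(b.genome_pair[1], b.replicon_pair[0], b.replicon_pair[1],
             b.ref_rank_span[0], b.ref_rank_span[1],
             b.other_rank_span[0], b.other_rank_span[1],
             b.orientation, len(b)) for b in blocks]
    return pd.DataFrame(rows, columns=[
        "other_genome", "ref_replicon", "other_replicon",
        "ref_start_rank", "ref_end_rank", "other_start_rank",
        "other_end_rank", "orientation", "n_pairs"])
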