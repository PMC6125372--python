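"""Independent brute-force oracles used to check the implementation.

Each oracle is written against the operation's definition, not its
implementation: local alignment by exhaustive scoring of substring pairs
(memoized three-state recursion, not Biopython), RBH by direct argmax
scanning, families by union-find (not networkx), synteny blocks by
whole-interval validity checks, window profiles by recounting.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(seq_a: str, seq_b: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Optimal local-alignment score by exhaustively scoring every pair of
    substrings with a three-state affine recursion (gap of length L costs
    gap_open + L*gap_extend).  Exponential bookkeeping tamed only by
    memoization; intended for sequences of length <= ~8."""

    def global_affine(x: str, y: str) -> float:
        @lru_cache(maxsize=None)
        def rec(i: int, j: int, state: str) -> float:
            if i == len(x) and j == len(y):
                return 0.0
            best = float("-inf")
            if i < len(x) and j < len(y):
                best = max(best,
                           _BLOSUM62[x[i], y[j]] + rec(i + 1, j + 1, "M"))
            if i < len(x):
                cost = gap_extend if state == "X" else gap_open + gap_extend
                best = max(best, -cost + rec(i + 1, j, "X"))
            if j < len(y):
                cost = gap_extend if state == "Y" else gap_open + gap_extend
                best = max(best, -cost + rec(i, j + 1, "Y"))
            return best

        return rec(0, 0, "M")

    best = 0.0
    for i1 in range(len(seq_a)):
        for i2 in range(i1 + 1, len(seq_a) + 1):
            for j1 in range(len(seq_b)):
                for j2 in range(j1 + 1, len(seq_b) + 1):
                    best = max(best,
                               global_affine(seq_a[i1:i2], seq_b[j1:j2]))
    return best


def rbh_oracle(score: dict[tuple[str, str], float]) -> set[frozenset]:
    """RBH pairs from a (gene_a, gene_b) -> score mapping by direct argmax
    scanning; assumes all scores distinct."""
    a_genes = sorted({a for a, _ in score})
    b_genes = sorted({b for _, b in score})
    best_a = {}
    for a in a_genes:
        partners = [(s, b) for (aa, b), s in score.items() if aa == a]
        if partners:
            best_a[a] = max(partners)[1]
    best_b = {}
    for b in b_genes:
        partners = [(s, a) for (a, bb), s in score.items() if bb == b]
        if partners:
            best_b[b] = max(partners)[1]
    return {frozenset((a, b)) for a, b in best_a.items()
            if best_b.get(b) == a}


class UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_oracle(edges: list[tuple[str, str]]) -> set[frozenset]:
    uf = UnionFind()
    for a, b in edges:
        uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for node in uf.parent:
        groups.setdefault(uf.find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}


def _interval_valid(anchors, lo: int, hi: int, max_gap: int) -> bool:
    """Whole-interval collinearity check: one consistent direction, every
    consecutive step within the gap bound on both genomes."""
    if hi == lo:
        return True
    for direction in (1, -1):
        ok = True
        for idx in range(lo, hi):
            r1, o1 = anchors[idx]
            r2, o2 = anchors[idx + 1]
            if r2 - r1 - 1 > max_gap:
                ok = False
                break
            delta = (o2 - o1) * direction
            if delta <= 0 or delta - 1 > max_gap:
                ok = False
                break
        if ok:
            return True
    return False


def synteny_blocks_oracle(anchors: list[tuple[int, int]],
                          min_block_len: int = 3,
                          max_gap: int = 2) -> list[tuple[int, int]]:
    """Greedy left-to-right partition into maximal valid intervals using
    the whole-interval validity predicate; returns (lo, hi) index spans of
    emitted blocks over the reference-sorted anchor list."""
    anchors = sorted(anchors)
    blocks = []
    s = 0
    while s < len(anchors):
        j = s
        while j + 1 < len(anchors) and \
                _interval_valid(anchors, s, j + 1, max_gap):
            j += 1
        if j - s + 1 >= min_block_len:
            blocks.append((s, j))
        s = j + 1
    return blocks


def window_counts_oracle(calls: list[str], window: int,
                         ) -> list[tuple[int, int, int]]:
    """(start, up, down) for every window by direct recounting."""
    out = []
    for start in range(len(calls) - window + 1):
        seg = calls[start:start + window]
        out.append((start, seg.count("up"), seg.count("down")))
    return out
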