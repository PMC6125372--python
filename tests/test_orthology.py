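import math
from itertools import product

import numpy as np
import pytest

from orthocore.orthology import (AlignmentHit, OrthologyThresholds,
                                 align_local, bitscore_from_raw,
                                 build_families, copy_number_table,
                                 evalue_from_bitscore, filter_hits,
                                 genome_pair_hits, hit_passes,
                                 reciprocal_best_hits)

from conftest import make_genome
from oracles import components_oracle, rbh_oracle, sw_score_oracle


def make_hit(q="a", s="b", identity=0.9, cov_q=0.9, cov_s=0.9,
             evalue=1e-20, bitscore=100.0, raw=250):
    return AlignmentHit(query_gene=q, subject_gene=s, raw_score=raw,
                        bitscore=bitscore, evalue=evalue, identity=identity,
                        coverage_query=cov_q, coverage_subject=cov_s,
                        aln_length=100)


class TestAlignLocal:
    def test_exact_match_hand_example(self):
        # BLOSUM62 A<->A = +4, four matches, no gaps
        hit = align_local("AAAA", "AAAA")
        assert hit.raw_score == 16
        assert hit.identity == 1.0
        assert hit.coverage_query == 1.0
        assert hit.coverage_subject == 1.0

    @pytest.mark.parametrize("seq", ["MKWVTFISLLFLFSSAYS", "ACDEFGHIKLMN"])
    def test_self_alignment_is_identity(self, seq):
        hit = align_local(seq, seq)
        assert hit.identity == 1.0
        assert hit.coverage_query == 1.0
        assert hit.coverage_subject == 1.0

    def test_score_symmetric_under_swap(self):
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aa, size=rng.integers(5, 40)))
            b = "".join(rng.choice(aa, size=rng.integers(5, 40)))
            ha = align_local(a, b)
            hb = align_local(b, a)
            if ha is None:
                assert hb is None
            else:
                assert ha.raw_score == hb.raw_score

    def test_bad_residue_named(self):
        with pytest.raises(ValueError, match="B"):
            align_local("MKB", "MK")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "MK")

    def test_matches_exhaustive_enumeration_short_pairs(self):
        # all pairs over a 3-letter alphabet up to length 3, plus seeded
        # longer draws up to length 6
        alphabet = "AKW"
        seqs = [("".join(t)) for n in (1, 2, 3)
                for t in product(alphabet, repeat=n)]
        pairs = [(a, b) for a in seqs for b in seqs]
        rng = np.random.default_rng(11)
        for _ in range(60):
            a = "".join(rng.choice(list(alphabet),
                                   size=rng.integers(4, 7)))
            b = "".join(rng.choice(list(alphabet),
                                   size=rng.integers(4, 7)))
            pairs.append((a, b))
        checked = 0
        for a, b in pairs[:400] + pairs[-60:]:
            expected = sw_score_oracle(a, b)
            hit = align_local(a, b)
            got = 0 if hit is None else hit.raw_score
            assert got == expected, (a, b)
            checked += 1
        assert checked >= 400


class TestEvalue:
    def test_bitscore_log2mn_gives_E_one(self):
        m, n = 350, 420
        assert evalue_from_bitscore(math.log2(m * n), m, n) == \
            pytest.approx(1.0)

    def test_linear_in_search_space(self):
        e1 = evalue_from_bitscore(40.0, 300, 400)
        e2 = evalue_from_bitscore(40.0, 300, 800)
        assert e2 == pytest.approx(2 * e1)

    def test_strictly_decreasing_in_bitscore(self):
        es = [evalue_from_bitscore(b, 400, 400) for b in (10, 20, 30)]
        assert es[0] > es[1] > es[2]

    def test_gapped_blosum62_closed_form(self):
        # raw 100, lambda=0.267, K=0.041, m=n=400, computed by hand
        bits = (0.267 * 100 - math.log(0.041)) / math.log(2)
        expected = 400 * 400 * 2.0 ** (-bits)
        assert bitscore_from_raw(100) == pytest.approx(bits)
        assert evalue_from_bitscore(bitscore_from_raw(100), 400, 400) == \
            pytest.approx(expected)


class TestFilterHits:
    def test_identity_below_threshold_removed(self):
        hits = [make_hit(identity=0.34, cov_q=0.9, cov_s=0.9,
                         evalue=1e-10)]
        assert filter_hits(hits) == []

    def test_boundary_values_retained(self):
        hit = make_hit(identity=0.35, cov_q=0.60, cov_s=0.60, evalue=1e-5)
        assert filter_hits([hit]) == [hit]

    def test_symmetric_coverage_uses_minimum(self):
        hit = make_hit(cov_q=0.9, cov_s=0.5)
        assert filter_hits([hit]) == []
        assert filter_hits([hit], OrthologyThresholds(coverage_on="query")) \
            == [hit]

    def test_idempotent_and_matches_predicate_scan(self):
        rng = np.random.default_rng(3)
        hits = [make_hit(identity=rng.uniform(0, 1),
                         cov_q=rng.uniform(0, 1), cov_s=rng.uniform(0, 1),
                         evalue=10.0 ** rng.uniform(-30, 1))
                for _ in range(1000)]
        thresholds = OrthologyThresholds()
        kept = filter_hits(hits, thresholds)
        brute = [h for h in hits
                 if h.identity >= 0.35
                 and min(h.coverage_query, h.coverage_subject) >= 0.60
                 and h.evalue <= 1e-5]
        assert kept == brute
        assert filter_hits(kept, thresholds) == kept


def hits_from_matrix(scores):
    """Directional hits for a dict (a_gene, b_gene) -> bitscore."""
    hits = []
    for (a, b), s in scores.items():
        base = make_hit(q=a, s=b, bitscore=s)
        hits.append(base)
        hits.append(base.swapped())
    return hits


class TestRBH:
    def test_two_by_two_example(self):
        scores = {("a1", "b1"): 100.0, ("a1", "b2"): 50.0,
                  ("a2", "b2"): 80.0, ("a2", "b1"): 40.0}
        ga = make_genome("A", ["a1", "a2"])
        gb = make_genome("B", ["b1", "b2"])
        pairs = reciprocal_best_hits(ga, gb, hits_from_matrix(scores))
        assert {p.key() for p in pairs} == \
            {frozenset(("a1", "b1")), frozenset(("a2", "b2"))}

    def test_single_passing_hit(self):
        ga = make_genome("A", ["a1"])
        gb = make_genome("B", ["b1"])
        pairs = reciprocal_best_hits(ga, gb,
                                     hits_from_matrix({("a1", "b1"): 60.0}))
        assert len(pairs) == 1
        assert pairs[0].key() == frozenset(("a1", "b1"))

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            na, nb = rng.integers(1, 11, size=2)
            a_ids = [f"a{i}" for i in range(na)]
            b_ids = [f"b{j}" for j in range(nb)]
            scores = {}
            for a in a_ids:
                for b in b_ids:
                    if rng.random() < 0.7:
                        scores[(a, b)] = float(rng.uniform(30, 200))
            ga = make_genome("A", a_ids)
            gb = make_genome("B", b_ids)
            pairs = reciprocal_best_hits(ga, gb, hits_from_matrix(scores))
            assert {p.key() for p in pairs} == rbh_oracle(scores)

    def test_one_to_one_per_genome_pair(self):
        rng = np.random.default_rng(23)
        a_ids = [f"a{i}" for i in range(8)]
        b_ids = [f"b{j}" for j in range(8)]
        scores = {(a, b): float(rng.uniform(30, 200))
                  for a in a_ids for b in b_ids}
        pairs = reciprocal_best_hits(make_genome("A", a_ids),
                                     make_genome("B", b_ids),
                                     hits_from_matrix(scores))
        seen = [g for p in pairs for g in (p.gene_a, p.gene_b)]
        assert len(seen) == len(set(seen))


class FakePair:
    def __init__(self, a, b):
        self.gene_a, self.gene_b = a, b


class TestFamilies:
    GENOME_OF = staticmethod(lambda g: g.split("_")[0])

    def genomes_map(self, genes):
        return {g: self.GENOME_OF(g) for g in genes}

    def test_transitive_closure(self):
        pairs = [FakePair("A_1", "B_1"), FakePair("B_1", "C_1")]
        fams = build_families(pairs,
                              self.genomes_map(["A_1", "B_1", "C_1"]))
        assert len(fams) == 1
        assert fams[0].members == {"A_1", "B_1", "C_1"}
        assert fams[0].genome_copy_number == {"A": 1, "B": 1, "C": 1}

    def test_no_edges_no_multigenome_families(self):
        fams = build_families([], self.genomes_map(["A_1", "B_1"]))
        assert fams == []
        singletons = build_families([], self.genomes_map(["A_1", "B_1"]),
                                    include_singletons=True)
        assert all(len(f.members) == 1 for f in singletons)
        assert len(singletons) == 2

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            n = int(rng.integers(5, 101))
            genes = [f"G{i}_x" for i in range(n)]
            edges = []
            for _ in range(int(rng.integers(0, n))):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    edges.append((genes[i], genes[j]))
            fams = build_families([FakePair(a, b) for a, b in edges],
                                  self.genomes_map(genes))
            assert {frozenset(f.members) for f in fams} == \
                components_oracle(edges)

    def test_best_hit_recruitment_of_inparalog(self):
        # A_2 is A_1's duplicate: no RBH edge (B_1 pairs with A_1) but its
        # best filtered hit lands in the family, so it joins as copy 2
        pairs = [FakePair("A_1", "B_1")]
        hits = [make_hit(q="A_2", s="B_1", bitscore=90.0)]
        fams = build_families(pairs,
                              self.genomes_map(["A_1", "A_2", "B_1"]),
                              hits=hits)
        assert len(fams) == 1
        assert fams[0].members == {"A_1", "A_2", "B_1"}
        assert fams[0].genome_copy_number["A"] == 2

    def test_copy_number_table_sums_to_family_size(self):
        pairs = [FakePair("A_1", "B_1"), FakePair("A_3", "B_2")]
        hits = [make_hit(q="A_2", s="B_1", bitscore=90.0)]
        gm = self.genomes_map(["A_1", "A_2", "A_3", "B_1", "B_2"])
        fams = build_families(pairs, gm, hits=hits)
        genomes = [make_genome("A", ["A_1", "A_2", "A_3"]),
                   make_genome("B", ["B_1", "B_2"])]
        table = copy_number_table(fams, genomes)
        for fam in fams:
            assert table.loc[fam.family_id].sum() == len(fam.members)
        assert table.loc[fams[0].family_id, "A"] == 2


class TestGenomePairHits:
    def test_prefilter_does_not_change_filtered_hits(self):
        rng = np.random.default_rng(31)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        base = ["".join(rng.choice(aa, size=80)) for _ in range(6)]
        # genome B carries mutated copies of A's proteins
        mutated = []
        for seq in base:
            s = list(seq)
            for pos in rng.integers(0, 80, size=8):
                s[pos] = str(rng.choice(aa))
            mutated.append("".join(s))
        ga = make_genome("A", [f"a{i}" for i in range(6)],
                         {f"a{i}": base[i] for i in range(6)})
        gb = make_genome("B", [f"b{i}" for i in range(6)],
                         {f"b{i}": mutated[i] for i in range(6)})
        with_pf = genome_pair_hits(ga, gb, OrthologyThresholds())
        without_pf = genome_pair_hits(ga, gb,
                                      OrthologyThresholds(prefilter=False))
        key = lambda h: (h.query_gene, h.subject_gene)
        assert sorted(map(key, with_pf)) == sorted(map(key, without_pf))

    def test_hits_pass_thresholds(self, small_genome_set):
        genomes, _, _, _ = small_genome_set
        thresholds = OrthologyThresholds()
        hits = genome_pair_hits(genomes[0], genomes[2], thresholds)
        assert hits, "cross-group orthologs expected"
        assert all(hit_passes(h, thresholds) for h in hits)
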