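from __future__ import annotations

import numpy as np
import pytest

from _oracles import best_gapless_score, best_hits_bruteforce
from conftest import mutate, random_dna
from sitkit.align import AlignParams, align_pair, all_vs_all, best_hits, revcomp
from sitkit.io import ContigRecord, DataError, Hit


def contig(project: str, cid: str, seq: str) -> ContigRecord:
    return ContigRecord(project, cid, seq)


class TestAlignPair:
    def test_identical_copy(self, rng):
        seq = random_dna(rng, 300)
        hits = align_pair(contig("P1", "a", seq), contig("P2", "b", seq))
        (h,) = [h for h in hits if h.strand == "+"]
        assert (h.pident, h.aln_len, h.score) == (100.0, 300, 300)

    def test_three_substitutions(self, rng):
        seq = random_dna(rng, 300)
        chars = list(seq)
        for p in (60, 150, 240):  # interior, so extension spans the contig
            chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
        a, b = contig("P1", "a", seq), contig("P2", "b", "".join(chars))
        top = max(align_pair(a, b), key=lambda h: h.score)
        assert top.score == 294
        assert top.pident == pytest.approx(99.0)
        assert top.score == best_gapless_score(a.sequence, b.sequence)

    def test_random_pairs_share_nothing(self, rng):
        for _ in range(100):
            a = contig("P1", "a", random_dna(rng, 300))
            b = contig("P2", "b", random_dna(rng, 300))
            assert align_pair(a, b) == []

    def test_reverse_complement_found(self, rng):
        seq = random_dna(rng, 200)
        hits = align_pair(
            contig("P1", "a", seq), contig("P2", "b", revcomp(seq))
        )
        (h,) = [h for h in hits if h.strand == "-"]
        assert h.score == 200
        assert (h.s_start, h.s_end) == (1, 200)

    def test_masked_seed_blocked_but_extension_allowed(self, rng):
        core = random_dna(rng, 100)
        # fully lowercase copy cannot seed at all
        a = contig("P1", "a", core)
        b_masked = contig("P2", "b", core.lower())
        assert align_pair(a, b_masked) == []
        # partially masked copy seeds in the uppercase region and extends
        half_masked = core[:50].lower() + core[50:]
        h = max(
            align_pair(a, contig("P2", "c", half_masked)),
            key=lambda h: h.score,
        )
        assert h.aln_len == 100 and h.score == 100

    def test_same_project_rejected(self, rng):
        a = contig("P1", "a", random_dna(rng, 50))
        with pytest.raises(DataError):
            align_pair(a, a)

    def test_score_pident_bounds(self, rng):
        for sub_rate in (0.0, 0.02, 0.05):
            seq = random_dna(rng, 400)
            other = mutate(rng, seq, int(sub_rate * 400))
            for h in align_pair(contig("P1", "a", seq), contig("P2", "b", other)):
                assert 0.0 < h.pident <= 100.0
                assert h.score <= h.aln_len


def make_hit(qp, qc, sp, sc, score, pident=99.0, aln_len=200):
    return Hit(qp, qc, sp, sc, pident, aln_len, score, 1, aln_len, 1, aln_len)


class TestBestHits:
    def test_max_per_pair(self):
        hits = [
            make_hit("P1", "c1", "P2", "c9", 550),
            make_hit("P1", "c1", "P2", "c9", 300),
        ]
        assert best_hits(hits) == [hits[0]]

    def test_unordered_pair_semantics(self):
        hits = [
            make_hit("P1", "c1", "P2", "c9", 400),
            make_hit("P2", "c9", "P1", "c1", 410),
        ]
        assert best_hits(hits) == [hits[1]]

    def test_matches_bruteforce_on_random_hits(self, rng):
        pairs = [(f"c{i}", f"d{i % 25}") for i in range(50)]
        hits = []
        for _ in range(1000):
            qc, sc = pairs[int(rng.integers(50))]
            if rng.random() < 0.5:
                hits.append(make_hit("P1", qc, "P2", sc,
                                     int(rng.integers(64, 500)),
                                     float(rng.integers(80, 101))))
            else:
                hits.append(make_hit("P2", sc, "P1", qc,
                                     int(rng.integers(64, 500)),
                                     float(rng.integers(80, 101))))
        assert best_hits(hits) == best_hits_bruteforce(hits)

    def test_input_order_irrelevant(self, rng):
        hits = [
            make_hit("P1", f"c{i}", "P2", f"d{i}", int(rng.integers(64, 500)))
            for i in range(40)
        ]
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert best_hits(hits) == best_hits(shuffled)


class TestAllVsAll:
    def test_planted_pair_found_once(self, rng):
        seq = random_dna(rng, 400)
        projects = {
            "P1": [contig("P1", "c1", seq), contig("P1", "c2", random_dna(rng, 400))],
            "P2": [contig("P2", "c1", seq), contig("P2", "c2", random_dna(rng, 400))],
        }
        hits = all_vs_all(projects)
        assert len(hits) == 1
        assert hits[0].pident == 100.0

    def test_disjoint_projects_empty(self, rng):
        projects = {
            f"P{i}": [contig(f"P{i}", "c1", random_dna(rng, 300))]
            for i in range(1, 4)
        }
        assert all_vs_all(projects) == []

    def test_single_project_rejected(self, rng):
        with pytest.raises(DataError, match="2 projects"):
            all_vs_all({"P1": [contig("P1", "c1", random_dna(rng, 100))]})

    def test_symmetry_and_determinism(self, rng):
        seqs = {f"c{i}": random_dna(rng, 300) for i in range(5)}
        pa = [contig("A", cid, s) for cid, s in seqs.items()]
        pb = [contig("B", cid, mutate(rng, s, 6)) for cid, s in seqs.items()]
        forward = all_vs_all({"A": pa, "B": pb})
        backward = all_vs_all({"B": pb, "A": pa})
        permuted = all_vs_all({"A": pa[::-1], "B": pb[::-1]})
        assert forward == backward == permuted
        assert forward  # the mutated copies do align

    def test_equals_per_pair_alignment(self, rng):
        pa = [contig("A", f"c{i}", random_dna(rng, 250)) for i in range(8)]
        pb = [
            contig("B", f"c{i}", mutate(rng, pa[i].sequence, 3) if i < 4
                   else random_dna(rng, 250))
            for i in range(8)
        ]
        raw = []
        for a in pa:
            for b in pb:
                raw.extend(align_pair(a, b))
        assert all_vs_all({"A": pa, "B": pb}) == best_hits(raw)


class TestOracleEquivalence:
    def test_top_scores_match_all_diagonal_scan(self, rng):
        """Aligner top scores equal the exhaustive Kadane diagonal scan on
        random <=200 nt pairs (related pairs planted among unrelated)."""
        params = AlignParams()
        for trial in range(200):
            n = int(rng.integers(80, 201))
            a_seq = random_dna(rng, n)
            if trial % 2 == 0:
                b_seq = mutate(rng, a_seq, int(rng.integers(0, max(1, n // 20))))
                if rng.random() < 0.3:
                    b_seq = revcomp(b_seq)
            else:
                b_seq = random_dna(rng, n)
            hits = align_pair(
                contig("P1", "a", a_seq), contig("P2", "b", b_seq), params
            )
            got = max((h.score for h in hits), default=0)
            expected = best_gapless_score(a_seq, b_seq)
            if expected < params.min_score:
                expected = 0
            assert got == expected, (trial, a_seq, b_seq)
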