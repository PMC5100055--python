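from __future__ import annotations

import numpy as np
import pytest

from _oracles import bin_bruteforce, threshold_bruteforce
from conftest import random_dna
from sitkit.decontam import (
    DecontamConfig,
    PairHistogram,
    arbitrate_pair,
    build_pair_histogram,
    compute_rpkm,
    detect_threshold,
    pident_bin,
    purge,
    qualify_hit,
    run_decontam,
)
from sitkit.io import ContigRecord, DataError, ExpressionRecord, Hit, ProteinRecord

CFG = DecontamConfig()
PAIR = frozenset({"P1", "P2"})


def hit(pident: float, aln_len: int = 200) -> Hit:
    return Hit("P1", "q", "P2", "s", pident, aln_len, aln_len, 1, aln_len,
               1, aln_len)


def hist_from(counts: dict[int, int]) -> PairHistogram:
    arr = np.zeros(101, dtype=np.int64)
    for b, c in counts.items():
        arr[b] = c
    return PairHistogram(PAIR, arr)


class TestQualifyHit:
    def test_absolute_length_arm(self):
        assert qualify_hit(hit(99.0, 160), 1000, 900, CFG)

    def test_fraction_of_shorter_arm(self):
        assert qualify_hit(hit(99.0, 100), 180, 1000, CFG)

    def test_fails_both_arms(self):
        assert not qualify_hit(hit(99.0, 100), 250, 1000, CFG)

    def test_corrupt_hit_rejected(self):
        with pytest.raises(DataError, match="exceeds"):
            qualify_hit(hit(99.0, 300), 250, 1000, CFG)


class TestHistogram:
    def test_binning_round_half_up(self):
        h = build_pair_histogram(
            [hit(100.0), hit(99.7), hit(99.4), hit(85.2)], PAIR
        )
        assert h.counts[100] == 2  # 99.7 rounds up into the 100 bin
        assert h.counts[99] == 1
        assert h.counts[85] == 1
        assert h.n_hits == 4

    def test_empty(self):
        h = build_pair_histogram([], PAIR)
        assert h.n_hits == 0 and not h.counts.any()

    def test_conservation_and_oracle(self, rng):
        pidents = rng.uniform(0, 100, size=10_000)
        hits = [hit(p) for p in pidents]
        h = build_pair_histogram(hits, PAIR)
        assert h.n_hits == 10_000
        expected = np.zeros(101, dtype=np.int64)
        for p in pidents:
            expected[bin_bruteforce(p)] += 1
        assert (h.counts == expected).all()

    def test_wrong_pair_rejected(self):
        with pytest.raises(DataError):
            build_pair_histogram([hit(99.0)], frozenset({"P1", "P3"}))

    @pytest.mark.parametrize(
        "pident,expected", [(99.5, 100), (99.49, 99), (0.2, 0), (100.0, 100)]
    )
    def test_bin_rule(self, pident, expected):
        assert pident_bin(pident) == expected


class TestDetectThreshold:
    def test_worked_trace(self):
        h = hist_from({100: 50, 99: 10, 98: 8, 97: 6, 96: 5, 95: 5, 94: 7})
        r = detect_threshold(h)
        assert r.contaminated and not r.fallback_used
        assert r.threshold_bin == 96

    def test_no_peak_no_contamination(self):
        r = detect_threshold(hist_from({100: 5, 99: 9, 85: 40}))
        assert not r.contaminated and r.threshold_bin is None

    def test_zero_bins_terminate_scan(self):
        r = detect_threshold(hist_from({100: 50, 99: 10}))
        assert r.contaminated and r.threshold_bin == 98

    def test_fallback_when_no_plateau(self):
        # counts strictly decreasing toward lower bins: no triple ever
        # satisfies counts[b-1] >= counts[b]
        counts = {b: b for b in range(2, 100)}
        counts[100] = 500
        with pytest.warns(UserWarning, match="plateau"):
            r = detect_threshold(hist_from(counts))
        assert r.contaminated and r.fallback_used
        assert r.threshold_bin == 1  # lowest populated bin (2) minus one

    def test_matches_bruteforce_on_random_histograms(self, rng):
        for _ in range(300):
            n_bins = int(rng.integers(1, 12))
            counts = {
                int(b): int(rng.integers(0, 100))
                for b in rng.integers(0, 101, size=n_bins)
            }
            arr = np.zeros(101, dtype=np.int64)
            for b, c in counts.items():
                arr[b] = c
            r = detect_threshold(PairHistogram(PAIR, arr))
            expected = threshold_bruteforce(arr)
            assert (r.contaminated, r.threshold_bin, r.fallback_used) == expected


class TestRpkm:
    def test_closed_form(self):
        assert compute_rpkm(100, 1000, 1_000_000) == pytest.approx(100.0)

    def test_zero_reads(self):
        assert compute_rpkm(0, 500, 10) == 0.0

    def test_independent_recomputation(self):
        expected = 123 / 777 / 9_876_543 * 1e9
        assert compute_rpkm(123, 777, 9_876_543) == pytest.approx(
            expected, rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            compute_rpkm(1, 0, 100)
        with pytest.raises(DataError):
            compute_rpkm(1, 100, 0)


class TestArbitratePair:
    def test_ratio_winner(self):
        a, b = arbitrate_pair(("P1", "x", 500.0), ("P2", "y", 20.0), CFG)
        assert a == ("retained", "rpkm_ratio_winner")
        assert b == ("discarded", "rpkm_ratio_loser")

    def test_both_high_expression_retained(self):
        a, b = arbitrate_pair(("P1", "x", 12_000.0), ("P2", "y", 11_000.0), CFG)
        assert a == ("retained", "rpkm_high_expression")
        assert b == ("retained", "rpkm_high_expression")

    def test_default_both_discarded(self):
        a, b = arbitrate_pair(("P1", "x", 50.0), ("P2", "y", 40.0), CFG)
        assert a == b == ("discarded", "default_both")

    def test_zero_rpkm_partner_counts_as_ratio_win(self):
        a, b = arbitrate_pair(("P1", "x", 5.0), ("P2", "y", 0.0), CFG)
        assert a == ("retained", "rpkm_ratio_winner")
        assert b == ("discarded", "rpkm_ratio_loser")

    def test_both_zero_discarded(self):
        a, b = arbitrate_pair(("P1", "x", 0.0), ("P2", "y", 0.0), CFG)
        assert a == b == ("discarded", "default_both")


def planted_scenario(rng, donor_rpkm=500.0, copy_rpkm=20.0):
    """Two projects sharing one verbatim contig copy plus random filler."""
    planted = random_dna(rng, 600)
    projects = {
        "P1": [ContigRecord("P1", "c1", planted),
               ContigRecord("P1", "c2", random_dna(rng, 500))],
        "P2": [ContigRecord("P2", "c1", planted),
               ContigRecord("P2", "c2", random_dna(rng, 500))],
    }
    total = 1_000_000
    counts = []
    for label, rpkm_planted in (("P1", donor_rpkm), ("P2", copy_rpkm)):
        for contig in projects[label]:
            rpkm = rpkm_planted if contig.contig_id == "c1" else 30.0
            counts.append(ExpressionRecord(
                label, contig.contig_id,
                int(round(rpkm * contig.length * total / 1e9)), total,
            ))
    hits = [
        Hit("P1", "c1", "P2", "c1", 100.0, 600, 600, 1, 600, 1, 600),
    ]
    return projects, hits, counts


class TestRunDecontam:
    def test_donor_retained_copy_discarded(self, rng):
        projects, hits, counts = planted_scenario(rng)
        result = run_decontam(projects, hits, counts, CFG)
        assert result.decisions[("P1", "c1")].status == "retained"
        assert result.decisions[("P1", "c1")].reason == "rpkm_ratio_winner"
        assert result.decisions[("P2", "c1")].status == "discarded"
        assert result.decisions[("P2", "c2")].status == "retained"
        (t,) = result.thresholds
        assert t.contaminated and t.threshold_bin == 99

    def test_excluded_pair_contributes_no_flags(self, rng):
        projects, hits, counts = planted_scenario(rng)
        cfg = DecontamConfig(excluded_pairs=frozenset({frozenset({"P1", "P2"})}))
        result = run_decontam(projects, hits, counts, cfg)
        assert all(d.status == "retained" for d in result.decisions.values())
        assert result.n_excluded_hits == 1

    def test_arbitration_disabled_discards_both(self, rng):
        projects, hits, _ = planted_scenario(rng)
        cfg = DecontamConfig(arbitration=False)
        result = run_decontam(projects, hits, None, cfg)
        assert result.decisions[("P1", "c1")].status == "discarded"
        assert result.decisions[("P2", "c1")].status == "discarded"

    def test_missing_counts_with_arbitration_rejected(self, rng):
        projects, hits, _ = planted_scenario(rng)
        with pytest.raises(DataError, match="mandatory"):
            run_decontam(projects, hits, None, CFG)

    def test_missing_expression_for_flagged_contig_named(self, rng):
        projects, hits, counts = planted_scenario(rng)
        counts = [c for c in counts if (c.project, c.contig_id) != ("P2", "c1")]
        with pytest.raises(DataError, match=r"P2\|c1"):
            run_decontam(projects, hits, counts, CFG)

    def test_input_order_irrelevant(self, rng):
        projects, hits, counts = planted_scenario(rng)
        r1 = run_decontam(projects, hits, counts, CFG)
        shuffled = {
            "P2": projects["P2"][::-1], "P1": projects["P1"][::-1]
        }
        r2 = run_decontam(shuffled, hits, list(reversed(counts)), CFG)
        assert {
            k: (d.status, d.reason) for k, d in r1.decisions.items()
        } == {k: (d.status, d.reason) for k, d in r2.decisions.items()}

    def test_qualification_filters_short_hits(self, rng):
        projects, hits, counts = planted_scenario(rng)
        short = [
            Hit("P1", "c1", "P2", "c1", 100.0, 80, 80, 1, 80, 1, 80)
        ]  # 80 < 150 and 80 < 0.5 * 600
        result = run_decontam(projects, short, counts, CFG)
        assert all(d.status == "retained" for d in result.decisions.values())


class TestPurge:
    def make_inputs(self, rng):
        contigs = [ContigRecord("P1", f"c{i}", random_dna(rng, 60))
                   for i in range(10)]
        proteins = [
            ProteinRecord("P1", "c3.p1", "c3", "MKLV"),
            ProteinRecord("P1", "c3.p2", "c3", "MNPQ"),
            ProteinRecord("P1", "c7.p1", "c7", "MAAA"),
        ]
        from sitkit.decontam import ContigDecision

        decisions = {
            ("P1", c.contig_id): ContigDecision(
                "P1", c.contig_id,
                "discarded" if c.contig_id in {"c1", "c3", "c8"} else "retained",
                "default_both" if c.contig_id in {"c1", "c3", "c8"}
                else "not_flagged",
            )
            for c in contigs
        }
        return contigs, proteins, decisions

    def test_exact_partition(self, rng):
        contigs, proteins, decisions = self.make_inputs(rng)
        result = purge(contigs, proteins, decisions)
        assert len(result.retained_nt) == 7 and len(result.purged_nt) == 3
        assert result.retained_nt + result.purged_nt != contigs  # reordered
        assert sorted(
            c.contig_id for c in result.retained_nt + result.purged_nt
        ) == sorted(c.contig_id for c in contigs)
        # order preserved within each partition
        ids_in = [c.contig_id for c in contigs]
        for part in (result.retained_nt, result.purged_nt):
            ids = [c.contig_id for c in part]
            assert ids == [x for x in ids_in if x in set(ids)]

    def test_proteins_follow_their_contig(self, rng):
        contigs, proteins, decisions = self.make_inputs(rng)
        result = purge(contigs, proteins, decisions)
        assert {p.protein_id for p in result.purged_aa} == {"c3.p1", "c3.p2"}
        assert {p.protein_id for p in result.retained_aa} == {"c7.p1"}

    def test_unlinked_protein_fail_open(self, rng):
        contigs, _, decisions = self.make_inputs(rng)
        orphan = [ProteinRecord("P1", "ghost.p1", "ghost", "MW")]
        with pytest.warns(UserWarning, match="ghost"):
            result = purge(contigs, orphan, decisions)
        assert result.retained_aa == orphan
        assert result.report["proteins_unlinked"] == 1

    def test_empty_discard_set(self, rng):
        contigs, proteins, _ = self.make_inputs(rng)
        from sitkit.decontam import ContigDecision

        decisions = {
            ("P1", c.contig_id): ContigDecision("P1", c.contig_id)
            for c in contigs
        }
        result = purge(contigs, proteins, decisions)
        assert result.purged_nt == [] and result.purged_aa == []
        assert result.report["contigs_retained"] == 10
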