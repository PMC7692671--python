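"""5'-end pileups, spanning queries, SAM I/O and the fixture mapper."""

import numpy as np
import pytest

from ptseq.genome import MotifSite, ReferenceSequence, reverse_complement
from ptseq.pileup import (Alignment, EndPileup, build_end_pileup,
                          count_ends_at, count_spanning, five_prime_end,
                          naive_align, parse_sam, write_sam)
from ptseq.qc import SequencedRead


def brute_force_end_count(alignments, position, strand):
    return sum(1 for a in alignments if five_prime_end(a) == (position, strand))


def brute_force_spanning(alignments, site):
    n = 0
    for a in alignments:
        fp, _ = five_prime_end(a)
        if (a.start <= site.start and a.end >= site.start + 4
                and fp not in (site.plus_cleavage, site.minus_cleavage)):
            n += 1
    return n


def random_alignments(rng, n, L=500):
    out = []
    for i in range(n):
        start = int(rng.integers(0, L - 60))
        length = int(rng.integers(20, 60))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(Alignment(f"r{i}", "c", start, start + length, strand))
    return out


class TestFivePrimeEnd:
    def test_plus_is_start_minus_is_end_minus_one(self):
        a = Alignment("r", "c", 10, 60, "+")
        b = Alignment("r", "c", 10, 60, "-")
        assert five_prime_end(a) == (10, "+")
        assert five_prime_end(b) == (59, "-")


class TestEndPileup:
    def test_counts_and_conservation(self):
        alns = [Alignment(f"r{i}", "c", 10, 60, "+") for i in range(3)]
        alns.append(Alignment("m", "c", 10, 60, "-"))
        pup = build_end_pileup(alns, {"c": 100})
        assert count_ends_at(pup, 10, "+") == 3
        assert count_ends_at(pup, 59, "-") == 1
        assert count_ends_at(pup, 42, "+") == 0
        assert pup.total_end_count() == pup.n_alignments == 4

    def test_empty_input(self):
        pup = build_end_pileup([], {"c": 50})
        assert pup.total_end_count() == 0
        assert count_spanning(pup, MotifSite.at("c", 10, "GAAC", 50)) == 0

    def test_order_independence(self, rng):
        alns = random_alignments(rng, 200)
        shuffled = list(alns)
        rng.shuffle(shuffled)
        a = build_end_pileup(alns, {"c": 500})
        b = build_end_pileup(shuffled, {"c": 500})
        site = MotifSite.at("c", 100, "GAAC", 500)
        assert np.array_equal(a.strand_track("c", "+"), b.strand_track("c", "+"))
        assert np.array_equal(a.strand_track("c", "-"), b.strand_track("c", "-"))
        assert a.count_spanning(site) == b.count_spanning(site)

    def test_matches_brute_force(self, rng):
        alns = random_alignments(rng, 200)
        pup = build_end_pileup(alns, {"c": 500})
        for pos in range(0, 500, 7):
            for strand in "+-":
                assert count_ends_at(pup, pos, strand) == \
                    brute_force_end_count(alns, pos, strand)
        for start in range(0, 490, 11):
            site = MotifSite.at("c", start, "GAAC", 500)
            assert count_spanning(pup, site) == \
                brute_force_spanning(alns, site)

    def test_spanning_excludes_cleavage_point_ends(self):
        site = MotifSite.at("c", 10, "GAAC", 100)
        covering = Alignment("a", "c", 0, 50, "+")       # 5' end at 0
        at_plus_cleavage = Alignment("b", "c", 0, site.plus_cleavage + 1, "-")
        pup = build_end_pileup([covering, at_plus_cleavage], {"c": 100})
        # the minus read's 5' end is exactly the plus cleavage point, but it
        # cannot contain the 4-mer anyway; the covering read spans
        assert count_spanning(pup, site) == 1
        # a minus read over the whole site whose 5' end hits minus_cleavage
        # is an end observation, not a spanning one
        end_read = Alignment("e", "c", 0, site.minus_cleavage + 1, "-")
        pup2 = build_end_pileup([covering, end_read], {"c": 100})
        assert count_spanning(pup2, site) == 1

    def test_mapq_and_tag_filters(self):
        alns = [Alignment("a", "c", 5, 40, "+", mapq=0, tagged=False),
                Alignment("b", "c", 5, 40, "+", mapq=60, tagged=True)]
        assert build_end_pileup(alns, {"c": 50}).count_ends_at(5, "+") == 2
        assert build_end_pileup(alns, {"c": 50},
                                mapq_floor=30).count_ends_at(5, "+") == 1
        assert build_end_pileup(alns, {"c": 50},
                                tagged_only=True).count_ends_at(5, "+") == 1


class TestSamIO:
    def test_round_trip_and_flags(self, tmp_path):
        alns = [Alignment("f", "c", 10, 60, "+", mapq=50),
                Alignment("r", "c", 10, 60, "-", mapq=60, tagged=True)]
        path = tmp_path / "a.sam"
        write_sam(alns, {"c": 100}, path)
        back = parse_sam(path)
        assert [(a.read_id, a.start, a.end, a.strand, a.mapq, a.tagged)
                for a in back] == \
            [("f", 10, 60, "+", 50, False), ("r", 10, 60, "-", 60, True)]

    def test_secondary_and_unmapped_excluded(self, tmp_path):
        path = tmp_path / "a.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c\tLN:100\n"
            "p\t0\tc\t11\t60\t50M\t*\t0\t0\t*\t*\n"
            "s\t256\tc\t11\t60\t50M\t*\t0\t0\t*\t*\n"
            "u\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
        back = parse_sam(path)
        assert [a.read_id for a in back] == ["p"]
        assert (back[0].start, back[0].end) == (10, 60)

    def test_missing_header_errors(self, tmp_path):
        path = tmp_path / "b.sam"
        path.write_text("p\t0\tc\t11\t60\t50M\t*\t0\t0\t*\t*\n")
        with pytest.raises(Exception):
            parse_sam(path)


class TestNaiveAlign:
    ref = ReferenceSequence(
        "c", "".join(np.random.default_rng(0).choice(list("ACGT"), size=400)))

    def test_forward_and_reverse_placement(self):
        fwd = SequencedRead("f", self.ref.seq[100:150], "F" * 50)
        rev = SequencedRead("r", reverse_complement(self.ref.seq[100:150]),
                            "F" * 50)
        alns, dropped = naive_align([fwd, rev], self.ref)
        assert [(a.read_id, a.start, a.end, a.strand) for a in alns] == \
            [("f", 100, 150, "+"), ("r", 100, 150, "-")]
        assert sum(dropped.values()) == 0

    def test_ambiguous_and_unaligned_dropped(self):
        seq = self.ref.seq[:50] + self.ref.seq[:50] + self.ref.seq[50:]
        double = ReferenceSequence("c", seq)
        ambiguous = SequencedRead("a", seq[:30], "F" * 30)
        novel = SequencedRead("n", "A" * 30, "F" * 30)
        alns, dropped = naive_align([ambiguous, novel], double)
        assert alns == []
        assert dropped["ambiguous"] == 1 and dropped["unaligned"] == 1

    def test_tag_flag_carried(self):
        read = SequencedRead("t", self.ref.seq[10:60], "F" * 50, tagged=True)
        alns, _ = naive_align([read], self.ref)
        assert alns[0].tagged
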