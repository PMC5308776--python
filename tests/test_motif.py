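"""Motif engine: degenerate matching, scanning, pairing, orientations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriscan.motif import (MotifSite, classify_orientation, collapse_pairs,
                           enumerate_pairs, iupac_match, make_pair,
                           reverse_complement, scan_sites, scrambled_patterns)

from oracles import (oracle_pairs, oracle_revcomp, oracle_scan, random_genome)

dna = st.text(alphabet="ACGT", min_size=1, max_size=50)
iupac = st.text(alphabet="ACGTRYMKSWBDHVN", min_size=1, max_size=20)


class TestIupacMatch:
    @pytest.mark.parametrize("window,pattern,expected", [
        ("GTAAATA", "RYMAAYA", True),    # the distal ARS607 Fkh1/2 site
        ("GATCCTA", "RYMAAYA", False),   # its knockout mutation
        ("ATAAACA", "RYMAAYA", True),    # reversal product of TGTTTAT
        ("TGTTTAT", "RYMAAYA", False),   # minus-strand site: no forward match
        ("AAAAAAA", "NNNNNNN", False),   # N never matches, even N-vs-N
        ("GTANATA", "RYMAAYA", False),   # N in the window never matches
        ("gtaaata", "RYMAAYA", True),    # soft-masked bases are scanned
    ])
    def test_examples(self, window, pattern, expected):
        assert iupac_match(window, pattern) is expected

    def test_length_mismatch_and_bad_characters_raise(self):
        with pytest.raises(ValueError):
            iupac_match("GTAAAT", "RYMAAYA")
        with pytest.raises(ValueError):
            iupac_match("GTAXATA", "RYMAAYA")
        with pytest.raises(ValueError):
            iupac_match("GTAAATA", "RYMAAXA")

    @given(window=st.text(alphabet="ACGTN", min_size=7, max_size=7))
    def test_agrees_with_positional_oracle(self, window):
        from oracles import oracle_window_match
        expected = "N" not in window and oracle_window_match(window, "RYMAAYA")
        assert iupac_match(window, "RYMAAYA") is expected


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("TGTTTAT", "ATAAACA"),   # the 5' site reversal used at ARS305
        ("GTAAATA", "TATTTAC"),   # the 3' site reversal
        ("RYMAAYA", "TRTTKRY"),   # degenerate codes complement symbol-wise
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_character_raises(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")

    @given(seq=iupac)
    def test_involution_and_oracle(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq
        assert reverse_complement(seq) == oracle_revcomp(seq)


class TestScanSites:
    @pytest.mark.parametrize("genome,expected", [
        ({"c1": "GGTAAATAGG"}, [("c1", 1, "+", "GTAAATA")]),
        ({"c1": "GGTGTTTATGG"}, [("c1", 2, "-", "TGTTTAT")]),
        ({"c1": "CCCCCCCC"}, []),
    ])
    def test_examples(self, genome, expected):
        sites = scan_sites(genome, "RYMAAYA")
        assert [(s.chrom, s.start, s.strand, s.matched_seq) for s in sites] == expected

    def test_palindromic_compatible_window_yields_both_strands(self):
        # WSW is its own reverse complement, so every match is reported on
        # both strands at the same start
        sites = scan_sites({"c": "GACAG"}, "WSW")
        assert [(s.start, s.strand) for s in sites] == [(1, "+"), (1, "-")]

    def test_conservation_of_planted_sites_on_match_free_background(self):
        filler = "C" * 40
        genome = {"c": filler + "GTAAATA" + filler + "TGTTTAT" + filler}
        sites = scan_sites(genome, "RYMAAYA")
        assert [(s.start, s.strand) for s in sites] == [(40, "+"), (87, "-")]

    def test_matches_positional_oracle_on_random_genomes(self, rng):
        for trial in range(20):
            genome = random_genome(rng, {"cA": 300, "cB": 150}, n_frac=0.02)
            got = [(s.chrom, s.start, s.strand) for s in scan_sites(genome, "RYMAAYA")]
            assert sorted(got) == oracle_scan(genome, "RYMAAYA")

    def test_reverse_complement_genome_preserves_site_count(self, rng):
        genome = random_genome(rng, {"c": 5000})
        flipped = {"c": reverse_complement(genome["c"])}
        assert len(scan_sites(genome)) == len(scan_sites(flipped))


class TestOrientationAndPairs:
    @pytest.mark.parametrize("up,down,expected", [
        ("-", "+", "divergent"),       # native ARS305/ARS607 configuration
        ("+", "-", "convergent"),      # both sites rotated
        ("+", "+", "unidirectional"),
        ("-", "-", "unidirectional"),
    ])
    def test_classify(self, up, down, expected):
        assert classify_orientation(up, down) == expected

    def test_invalid_strand_raises(self):
        with pytest.raises(ValueError):
            classify_orientation("+", "*")

    def test_native_geometry_gap_72_divergent(self):
        up = MotifSite("c1", 0, "-")
        down = MotifSite("c1", 79, "+")
        pairs = enumerate_pairs([up, down], 62, 88)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.gap_bp, p.orientation, p.midpoint) == (72, "divergent", 43)
        assert enumerate_pairs([up, down], 62, 71) == []

    def test_chains_pair_only_adjacent_sites(self):
        # three sites each 72 bp apart: (A,B) and (B,C) qualify, (A,C) does
        # not (gap 151 > 88); sharing a site between pairs is allowed
        sites = [MotifSite("c", 0, "+"), MotifSite("c", 79, "+"),
                 MotifSite("c", 158, "+")]
        pairs = enumerate_pairs(sites, 62, 88)
        assert [(p.upstream.start, p.downstream.start) for p in pairs] == [(0, 79), (79, 158)]

    def test_cross_chromosome_sites_never_pair(self):
        sites = [MotifSite("c1", 0, "+"), MotifSite("c2", 79, "+")]
        assert enumerate_pairs(sites, 0, 1000) == []

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(10):
            genome = random_genome(rng, {"c": 3000})
            sites = scan_sites(genome)
            got = sorted((p.chrom, p.upstream.start, p.upstream.strand,
                          p.downstream.start, p.downstream.strand)
                         for p in enumerate_pairs(sites, 10, 120))
            hits = [(s.chrom, s.start, s.strand) for s in sites]
            assert got == oracle_pairs(hits, 10, 120)

    def test_orientation_counts_invariant_under_genome_reverse_complement(self, rng):
        from collections import Counter
        genome = random_genome(rng, {"c": 20_000})
        flipped = {"c": reverse_complement(genome["c"])}
        def counts(g):
            pairs = enumerate_pairs(scan_sites(g), 62, 88)
            return Counter(p.orientation for p in pairs)
        assert counts(genome) == counts(flipped)

    def test_collapse_merges_doubled_site_pairs(self):
        up1 = MotifSite("c", 0, "-")
        up2 = MotifSite("c", 3, "-")   # overlapping "doubled" upstream site
        down = MotifSite("c", 79, "+")
        pairs = enumerate_pairs([up1, up2, down], 62, 88)
        assert len(pairs) == 2
        assert len(collapse_pairs(pairs)) == 1


class TestScrambles:
    def test_published_scrambles_and_permutation_property(self):
        patterns = scrambled_patterns()
        assert patterns == ["YAAYMAR", "MAARYAY", "AAYMYAR"]
        assert all(sorted(p) == sorted("RYMAAYA") for p in patterns)

    def test_scramble_counts_statistically_indistinguishable(self, rng):
        # same symbol multiset => same iid hit probability; counts on a
        # 400-kb yeast-composition genome must agree within 3 SD
        genome = random_genome(rng, {"c": 400_000})
        n_positions = 2 * (400_000 - 6)
        p = (0.5 ** 4) * (0.31 ** 3)  # R,Y,M,Y are 0.5; three A's are 0.31
        sd = (n_positions * p * (1 - p)) ** 0.5
        ref = len(scan_sites(genome, "RYMAAYA"))
        for pattern in scrambled_patterns():
            count = len(scan_sites(genome, pattern))
            assert abs(count - ref) < 3 * (2 ** 0.5) * sd
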