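"""Construct mutagenesis: the published origin edits and their verification."""

import pytest

from oriscan.example_loci import (ARS305_ACS, ARS305_NATIVE_ACS, ARS607_ACS,
                                  DISTAL_SITE, PROXIMAL_SITE,
                                  synthetic_ars305, synthetic_ars607)
from oriscan.motif import reverse_complement
from oriscan.mutagenesis import (EditSpec, apply_edit, apply_edits,
                                 verify_construct)


class TestApplyEdit:
    def test_replace_is_pure_and_checked(self):
        seq = "CCGTAAATACC"
        out = apply_edit(seq, EditSpec("replace", 2, payload="GATCCTA",
                                       original="GTAAATA"))
        assert out == "CCGATCCTACC"
        assert seq == "CCGTAAATACC"

    def test_replace_with_wrong_original_names_offset_and_found(self):
        with pytest.raises(ValueError, match="offset 2, found 'GTAAATA'"):
            apply_edit("CCGTAAATACC", EditSpec("replace", 2, payload="X",
                                               original="GTAAAT" + "G"))

    def test_invert_equals_reverse_complement_and_is_involutive(self):
        seq = "CCTGTTTATCC"
        inv = EditSpec("invert", 2, length=7)
        once = apply_edit(seq, inv)
        assert once == "CC" + reverse_complement("TGTTTAT") + "CC" == "CCATAAACACC"
        assert apply_edit(once, inv) == seq

    def test_insert_then_delete_restores_original(self):
        seq = "AACCGGTT"
        out = apply_edits(seq, [EditSpec("insert", 4, payload="GCGCG"),
                                EditSpec("delete", 4, length=5)])
        assert out == seq

    def test_bad_edits_rejected(self):
        with pytest.raises(ValueError):
            EditSpec("replace", 0, payload="A")       # no expected original
        with pytest.raises(ValueError):
            EditSpec("invert", 0, length=0)
        with pytest.raises(ValueError):
            apply_edit("ACGT", EditSpec("delete", 2, length=10))
        with pytest.raises(ValueError):
            apply_edit("ACGT", EditSpec("insert", 9, payload="A"))


class TestPublishedSiteEdits:
    """Each printed mutation string flips exactly the intended motif call."""

    def test_distal_site_knockout_removes_only_that_site(self, ars607):
        report = verify_construct(ars607.seq, [
            EditSpec("replace", ars607.distal_start, payload="GATCCTA",
                     original="GTAAATA")])
        before = {(s.start, s.strand) for s in report.sites_before}
        after = {(s.start, s.strand) for s in report.sites_after}
        assert before - after == {(ars607.distal_start, "+")}
        assert after == {(ars607.proximal_start, "-")}
        assert report.pairs_after == []

    @pytest.mark.parametrize("which,wt,product", [
        ("proximal", "TGTTTAT", "ATAAACA"),
        ("distal", "GTAAATA", "TATTTAC"),
    ])
    def test_single_site_reversal_matches_printed_product(self, ars305, which, wt, product):
        start = ars305.proximal_start if which == "proximal" else ars305.distal_start
        edited = apply_edit(ars305.seq, EditSpec("invert", start, length=7))
        assert edited[start:start + 7] == product == reverse_complement(wt)

    def test_double_reversal_gives_convergent_pair_same_gap(self, ars305):
        report = verify_construct(ars305.seq, [
            EditSpec("invert", ars305.proximal_start, length=7),
            EditSpec("invert", ars305.distal_start, length=7)])
        assert len(report.pairs_after) == 1
        pair = report.pairs_after[0]
        assert pair.orientation == "convergent"
        assert pair.gap_bp == 72

    @pytest.mark.parametrize("wt,mut", [
        (ARS305_ACS, "TTTATATGGGTT"),        # ARS305 reporter-locus ACS edit
        (ARS607_ACS, "GTTTATATCCAG"),        # ARS607 reporter-locus ACS edit
        (ARS305_NATIVE_ACS, "TTTTAATACCC"),  # native ARS305/ARS737 ACS edit
    ])
    def test_acs_point_mutations_flip_only_the_acs_call(self, wt, mut):
        # build a construct whose flanks cannot contain consensus matches
        seq = "G" * 30 + wt + "C" * 30
        report = verify_construct(seq, [EditSpec("replace", 30, payload=mut,
                                                 original=wt)],
                                  acs_refs=[("acs", wt)])
        assert report.acs_intact == {"acs": False}
        assert len(report.sites_after) == len(report.sites_before)
        unedited = verify_construct(seq, [], acs_refs=[("acs", wt)])
        assert unedited.acs_intact == {"acs": True}

    def test_ars607_acs_edit_spares_the_overlapping_proximal_site(self, ars607):
        report = verify_construct(ars607.seq, [
            EditSpec("replace", ars607.acs_offset, payload="GTTTATATCCAG",
                     original=ARS607_ACS)],
            acs_refs=[("ARS607_ACS", ARS607_ACS)])
        assert report.acs_intact == {"ARS607_ACS": False}
        assert {(s.start, s.strand) for s in report.sites_after} == \
               {(ars607.proximal_start, "-"), (ars607.distal_start, "+")}


class TestSpacerEdits:
    """Insertions/deletions between the sites shift the gap by their length."""

    @pytest.mark.parametrize("ins_len", [5, 10, 15])
    def test_insertion_between_sites_grows_gap_exactly(self, ars607, ins_len):
        anchor = ars607.distal_start - 7  # 7 bp from the distal site
        report = verify_construct(ars607.seq, [
            EditSpec("insert", anchor, payload=("GC" * 8)[:ins_len])],
            gap_min=0, gap_max=400)
        assert len(report.pairs_after) == 1
        assert report.pairs_after[0].gap_bp == 72 + ins_len
        assert len(report.edited_seq) == len(ars607.seq) + ins_len

    @pytest.mark.parametrize("distance", [24, 2])
    def test_deletion_between_sites_shrinks_gap_by_10(self, ars607, distance):
        anchor = ars607.distal_start - distance - 10
        report = verify_construct(ars607.seq,
                                  [EditSpec("delete", anchor, length=10)],
                                  gap_min=0, gap_max=400)
        assert len(report.pairs_after) == 1
        assert report.pairs_after[0].gap_bp == 62

    def test_new_site_inserted_at_10bp_forms_short_gap_pair(self, ars607):
        # knock out the distal site, then supply a fresh GTAAATA 10 bp from
        # the proximal site
        edits = [
            EditSpec("replace", ars607.distal_start, payload="GATCCTA",
                     original="GTAAATA"),
            EditSpec("insert", ars607.proximal_start + 7 + 10, payload="GTAAATA"),
        ]
        report = verify_construct(ars607.seq, edits, gap_min=0, gap_max=400)
        assert len(report.pairs_after) == 1
        assert report.pairs_after[0].gap_bp == 10
        assert report.pairs_after[0].orientation == "divergent"

    def test_summary_mentions_pair_and_acs_state(self, ars607):
        report = verify_construct(ars607.seq, [],
                                  acs_refs=[("ARS607_ACS", ARS607_ACS)],
                                  gap_min=62, gap_max=88)
        text = report.summary()
        assert "divergent" in text and "gap 72" in text and "intact" in text
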