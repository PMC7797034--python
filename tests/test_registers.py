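"""Guide normalization, motif construction and register-shift classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirclip.registers import (
    CANONICAL_CLASSES,
    GBULGE_CLASSES,
    MirnaRegister,
    SiteClass,
    all_patterns,
    build_register,
    canonical_patterns,
    classify_site,
    cross_register_class,
    gbulge_patterns,
    map_bulge_span,
    read_registers_tsv,
)

from conftest import naive_motifs

guides = st.text(alphabet="ACGU", min_size=16, max_size=30)


class TestBuildRegister:
    def test_normalizes_case_and_dna(self):
        reg = build_register("x", "acgtACGTacgtACGTa", 0)
        assert reg.guide_seq == "ACGUACGUACGUACGUA"

    def test_mir132_guide_starts_with_printed_seed(self):
        reg = build_register("miR-132", "uaacagucuacagccaugGUCG", 0)
        assert reg.guide_seq.startswith("UAACAGUC")

    @pytest.mark.parametrize(
        "seq",
        ["ACGUN" + "A" * 12, "ACG U" + "A" * 12, "", "ACGU" * 2, "ACGU" * 10],
    )
    def test_rejects_bad_alphabet_or_length(self, seq):
        with pytest.raises(ValueError):
            build_register("bad", seq, 0)

    def test_rejects_extreme_offset(self):
        with pytest.raises(ValueError):
            build_register("x", "ACGU" * 5, 3)

    def test_extended_register_prefixes_base(self, register_pair):
        base, ext = register_pair
        assert ext.register_offset == base.register_offset + 1
        assert ext.guide_seq[1:] == base.guide_seq


class TestPatternConstruction:
    @pytest.mark.parametrize(
        "cls,motif",
        [
            (SiteClass.SEVENMER_M8, "GACUGUU"),
            (SiteClass.EIGHTMER, "GACUGUUA"),
            (SiteClass.SEVENMER_A1, "ACUGUUA"),
            (SiteClass.SIXMER, "ACUGUU"),
            (SiteClass.OFFSET_SIXMER, "GACUGU"),
            (SiteClass.GBULGE_7M8, "GACGUGUU"),
            (SiteClass.GBULGE_8MER, "GACGUGUUA"),
        ],
    )
    def test_mir132_motifs(self, mir132, cls, motif):
        pats = {p.site_class: p.motif for p in all_patterns(mir132)}
        assert pats[cls] == motif

    def test_mir122_seed_sevenmer(self, mir122):
        pats = {p.site_class: p.motif for p in canonical_patterns(mir122)}
        assert pats[SiteClass.SEVENMER_M8] == "ACACUCC"

    def test_polya_guide(self):
        reg = build_register("polyA", "A" * 16, 0)
        pats = {p.site_class: p.motif for p in all_patterns(reg)}
        assert pats[SiteClass.SEVENMER_M8] == "U" * 7
        assert pats[SiteClass.GBULGE_7M8] == "UUUGUUUU"

    @settings(max_examples=100, derandomize=True)
    @given(guides)
    def test_matches_naive_oracle(self, guide):
        reg = MirnaRegister("g", guide, 0)
        expected = naive_motifs(guide)
        got = {p.site_class: p.motif for p in all_patterns(reg)}
        assert got == expected

    @settings(max_examples=50, derandomize=True)
    @given(guides)
    def test_gbulge_one_longer_than_parent(self, guide):
        reg = MirnaRegister("g", guide, 0)
        pats = {p.site_class: p for p in all_patterns(reg)}
        assert len(pats[SiteClass.GBULGE_7M8].motif) == len(pats[SiteClass.SEVENMER_M8].motif) + 1
        assert len(pats[SiteClass.GBULGE_8MER].motif) == len(pats[SiteClass.EIGHTMER].motif) + 1
        assert pats[SiteClass.GBULGE_7M8].bulge_insert_index == 3


class TestClassify:
    @settings(max_examples=60, derandomize=True)
    @given(guides)
    def test_round_trip_each_class(self, guide):
        """classify_site on each class's own motif returns that class."""
        reg = MirnaRegister("g", guide, 0)
        for pat in all_patterns(reg):
            anchor = 1 if pat.site_class in (SiteClass.SEVENMER_A1, SiteClass.SIXMER) else 0
            window = "C" * anchor + pat.motif + "CC"
            got = classify_site(window, reg, anchor=0)
            # nested stronger motifs can only appear if the guide is degenerate;
            # the call must be at least as strong as the planted class
            order = list(CANONICAL_CLASSES) + list(GBULGE_CLASSES)
            assert got != SiteClass.NONE
            if got != pat.site_class:
                priority = {c: i for i, c in enumerate(
                    (SiteClass.EIGHTMER, SiteClass.GBULGE_8MER, SiteClass.SEVENMER_M8,
                     SiteClass.GBULGE_7M8, SiteClass.SEVENMER_A1, SiteClass.SIXMER,
                     SiteClass.OFFSET_SIXMER))}
                assert priority[got] < priority[pat.site_class]

    def test_round_trip_exact_on_fixture(self, mir132):
        for pat in all_patterns(mir132):
            a1_anchored = pat.site_class in (SiteClass.SEVENMER_A1, SiteClass.SIXMER)
            # place the motif so the nucleotide opposite g8 sits at anchor 0
            window = ("C" if a1_anchored else "") + pat.motif + "CC"
            assert classify_site(window, mir132, anchor=0) == pat.site_class

    def test_no_match_returns_none(self, mir132):
        assert classify_site("CCCCCCCCCCCC", mir132) == SiteClass.NONE

    def test_rejects_bad_alphabet(self, mir132):
        with pytest.raises(ValueError):
            classify_site("GACUGUUN", mir132)


class TestCrossRegister:
    def test_base_eightmer_under_extended(self, register_pair):
        base, ext = register_pair
        assert cross_register_class(SiteClass.EIGHTMER, base, ext, flank_3p="A") == SiteClass.EIGHTMER
        for nt in "CGU":
            assert (
                cross_register_class(SiteClass.EIGHTMER, base, ext, flank_3p=nt)
                == SiteClass.SEVENMER_M8
            )

    def test_extended_a1_weakens_under_base(self, register_pair):
        """A 7mer-A1 for the extended isoform pairs at most 6 contiguous nt
        of the base seed (g2-g7), so the base call is never m8-anchored: a
        favourable 5' flank can complete a 7mer-A1, never a 7mer-m8/8mer."""
        base, ext = register_pair
        weak = {SiteClass.SEVENMER_A1, SiteClass.SIXMER, SiteClass.OFFSET_SIXMER, SiteClass.NONE}
        comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
        g7_pairing = comp[base.guide(7)]
        for f1 in "ACGU":
            for f2 in "ACGU":
                got = cross_register_class(
                    SiteClass.SEVENMER_A1, ext, base, flank_5p=f1 + f2, flank_3p="C"
                )
                if f2 != g7_pairing:
                    assert got in weak
        # fully complementary 5' flanks extend the pairing to a base 8mer
        full = comp[base.guide(8)] + g7_pairing
        assert (
            cross_register_class(SiteClass.SEVENMER_A1, ext, base, flank_5p=full, flank_3p="C")
            == SiteClass.EIGHTMER
        )

    def test_rejects_non_adjacent_registers(self, register_pair):
        base, _ = register_pair
        with pytest.raises(ValueError):
            cross_register_class(SiteClass.EIGHTMER, base, base)

    def test_bulge_span_maps_one_position(self, register_pair):
        base, ext = register_pair
        assert map_bulge_span(base, ext, (5, 6)) == (6, 7)
        assert map_bulge_span(ext, base, (6, 7)) == (5, 6)


def test_read_registers_tsv(tmp_path):
    path = tmp_path / "regs.tsv"
    path.write_text(
        "name\tsequence\tregister_offset\n"
        "base\tUAAGGCACGCGGUGAAUGCC\t0\n"
        "ext\tUUAAGGCACGCGGUGAAUGCC\t1\n"
    )
    regs = read_registers_tsv(path)
    assert [r.name for r in regs] == ["base", "ext"]
    assert regs[1].register_offset == 1
    bad = tmp_path / "bad.tsv"
    bad.write_text("onlyname\n")
    with pytest.raises(ValueError):
        read_registers_tsv(bad)
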