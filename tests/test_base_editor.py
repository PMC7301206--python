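import itertools

import pytest

from bescan.base_editor import (
    AnnotatedGuide,
    Conversion,
    EditorSpec,
    annotate_guide,
    compute_edit_window,
    editable_positions,
    simulate_edits,
)
from bescan.genome_io import GeneFeature, GenomeRecord, reverse_complement
from bescan.guide_finder import GuideCandidate
from bescan.synthetic import CODON_LIST, CODON_TABLE_LOCAL, translate_naive


def make_candidate(strand, pam_start, contig_len=200, spacer_len=20):
    """Geometry-only candidate; sequences are irrelevant for window math."""
    if strand == "+":
        spacer_start, spacer_end = pam_start - spacer_len, pam_start
    else:
        spacer_start, spacer_end = pam_start + 3, pam_start + 3 + spacer_len
    return GuideCandidate(
        contig_id="c1",
        strand=strand,
        spacer_start=spacer_start,
        spacer_end=spacer_end,
        pam_start=pam_start,
        pam_end=pam_start + 3,
        spacer_seq="A" * spacer_len,
        pam_seq="AGG",
        seed_seq="A" * 13,
    )


class TestEditorSpec:
    def test_defaults(self):
        spec = EditorSpec()
        assert (spec.window_min, spec.window_max) == (13, 20)
        assert spec.conversion is Conversion.C_TO_T

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            EditorSpec(window_min=0, window_max=5)
        with pytest.raises(ValueError):
            EditorSpec(window_min=10, window_max=5)

    def test_window_vs_spacer(self):
        with pytest.raises(ValueError):
            EditorSpec(window_min=13, window_max=25).validate_against(20)


class TestComputeEditWindow:
    def test_plus_strand_defaults(self):
        cand = make_candidate("+", 100)
        assert compute_edit_window(cand, EditorSpec()) == (80, 88)

    def test_minus_strand_defaults(self):
        cand = make_candidate("-", 10)
        assert compute_edit_window(cand, EditorSpec()) == (25, 33)

    def test_degenerate_single_base_window(self):
        cand = make_candidate("+", 100)
        spec = EditorSpec(window_min=1, window_max=1)
        assert compute_edit_window(cand, spec) == (99, 100)
        cand = make_candidate("-", 10)
        assert compute_edit_window(cand, spec) == (13, 14)


class TestEditablePositions:
    def test_plus_strand_c_to_t(self):
        seq = "A" * 80 + "CCGA" + "A" * 116
        records = [GenomeRecord("c1", seq)]
        cand = make_candidate("+", 100)
        spec = EditorSpec(window_min=17, window_max=20)  # window [80, 84)
        assert editable_positions(cand, spec, records) == [80, 81]

    def test_minus_strand_complement_rule(self):
        seq = "A" * 25 + "GGAT" + "A" * 171
        records = [GenomeRecord("c1", seq)]
        cand = make_candidate("-", 10)
        spec = EditorSpec(window_min=13, window_max=16)  # window [25, 29)
        assert editable_positions(cand, spec, records) == [25, 26]

    def test_no_source_bases(self):
        records = [GenomeRecord("c1", "A" * 200)]
        cand = make_candidate("+", 100)
        assert editable_positions(cand, EditorSpec(), records) == []


def run_single_edit(codon, codon_pos, guide_strand, gene_strand, conversion):
    """Simulate editing exactly one base of one codon through the public API.

    The codon is placed as the second codon of a CDS; the guide's editable
    position is set to that base directly so every (codon, position)
    combination is reachable regardless of PAM geometry.
    """
    coding = "ATG" + codon + "GGCTAA"
    if gene_strand == "+":
        seq = "TTTTT" + coding + "TTTTT"
        genomic_pos = 5 + 3 + codon_pos
    else:
        seq = "TTTTT" + reverse_complement(coding) + "TTTTT"
        genomic_pos = 5 + len(coding) - 1 - (3 + codon_pos)
    feat = GeneFeature(locus_tag="g", strand=gene_strand,
                       intervals=((5, 5 + len(coding)),))
    records = [GenomeRecord("c1", seq, [feat])]
    cand = make_candidate(guide_strand, 100, contig_len=len(seq))
    guide = AnnotatedGuide(cand, 0, len(seq))
    guide.editable_positions = [genomic_pos]
    guide.outcomes = simulate_edits(guide, records)
    return guide.outcomes


class TestSimulateEdits:
    def test_caa_to_taa_stop_gain(self):
        outcomes = run_single_edit("CAA", 0, "+", "+", Conversion.C_TO_T)
        assert len(outcomes) == 1
        o = outcomes[0]
        assert (o.ref_codon, o.alt_codon) == ("CAA", "TAA")
        assert (o.ref_aa, o.alt_aa) == ("Q", "*")
        assert o.is_stop_gain

    def test_cga_to_tga_stop_gain(self):
        o = run_single_edit("CGA", 0, "+", "+", Conversion.C_TO_T)[0]
        assert (o.alt_codon, o.alt_aa) == ("TGA", "*")
        assert o.is_stop_gain

    def test_simultaneous_double_edit_one_outcome(self):
        # CCG with both Cs editable -> TTG in a single outcome (P -> L)
        coding = "ATGCCGGGCTAA"
        feat = GeneFeature(locus_tag="g", strand="+", intervals=((0, 12),))
        records = [GenomeRecord("c1", coding + "T" * 50, [feat])]
        cand = make_candidate("+", 40, contig_len=62)
        guide = AnnotatedGuide(cand, 0, 62)
        guide.editable_positions = [3, 4]
        outcomes = simulate_edits(guide, records)
        assert len(outcomes) == 1
        o = outcomes[0]
        assert (o.ref_codon, o.alt_codon) == ("CCG", "TTG")
        assert (o.ref_aa, o.alt_aa) == ("P", "L")
        assert not o.is_stop_gain and not o.is_synonymous

    def test_opposite_strand_tgg_stop_gain(self):
        # CDS on -, guide on +: forward C -> T appears as G -> A in TGG
        for pos in (1, 2):
            o = run_single_edit("TGG", pos, "+", "-", Conversion.C_TO_T)[0]
            assert o.ref_codon == "TGG"
            assert o.alt_codon in ("TAG", "TGA")
            assert o.is_stop_gain

    def test_intergenic_edit_no_outcome(self):
        records = [GenomeRecord("c1", "C" * 200)]
        cand = make_candidate("+", 100)
        guide = AnnotatedGuide(cand, 80, 88)
        guide.editable_positions = [82]
        assert simulate_edits(guide, records) == []

    def test_incomplete_terminal_codon_skipped(self, caplog):
        feat = GeneFeature(locus_tag="g", strand="+", intervals=((0, 7),))
        records = [GenomeRecord("c1", "ATGAAACA" + "T" * 50, [feat])]
        cand = make_candidate("+", 40, contig_len=58)
        guide = AnnotatedGuide(cand, 0, 58)
        guide.editable_positions = [6]  # inside the dangling 7th base codon
        with caplog.at_level("WARNING"):
            assert simulate_edits(guide, records) == []

    def test_multi_interval_cds(self):
        # join(0..3, 6..15): spliced coding = ATG CAA GGC TAA
        feat = GeneFeature(
            locus_tag="g", strand="+", intervals=((0, 3), (6, 15))
        )
        seq = "ATG" + "TT" + "TCAAGGCTAA" + "T" * 40
        records = [GenomeRecord("c1", seq, [feat])]
        cand = make_candidate("+", 40, contig_len=len(seq))
        guide = AnnotatedGuide(cand, 0, len(seq))
        guide.editable_positions = [6]  # first base of spliced codon 2 (CAA)
        o = simulate_edits(guide, records)[0]
        assert (o.ref_codon, o.alt_codon) == ("CAA", "TAA")
        assert o.codon_index == 1


class TestClassification:
    def test_stop_gain_flags(self):
        o = run_single_edit("CAG", 0, "+", "+", Conversion.C_TO_T)
        guide = AnnotatedGuide(make_candidate("+", 100), 80, 88)
        guide.outcomes = o
        assert guide.can_edit and guide.introduces_stop

    def test_synonymous_only_cannot_edit(self):
        o = run_single_edit("CTG", 0, "+", "+", Conversion.C_TO_T)
        assert o[0].alt_codon == "TTG" and o[0].is_synonymous
        guide = AnnotatedGuide(make_candidate("+", 100), 80, 88)
        guide.outcomes = o
        assert not guide.can_edit and not guide.introduces_stop

    def test_no_outcomes(self):
        guide = AnnotatedGuide(make_candidate("+", 100), 80, 88)
        assert not guide.can_edit and not guide.introduces_stop


def _expected_single_sub(codon, pos, ref_base, alt_base):
    if codon[pos] != ref_base:
        return None
    alt = codon[:pos] + alt_base + codon[pos + 1 :]
    return alt, CODON_TABLE_LOCAL[codon], CODON_TABLE_LOCAL[alt]


class TestGeneticCodeExhaustive:
    """All 64 codons x every single-base edit, against the naive code table."""

    @pytest.mark.parametrize(
        "conversion,gene_strand,ref_base,alt_base",
        [
            (Conversion.C_TO_T, "+", "C", "T"),  # coding-strand deamination
            (Conversion.C_TO_T, "-", "G", "A"),  # template-strand deamination
            (Conversion.A_TO_G, "+", "A", "G"),
            (Conversion.A_TO_G, "-", "T", "C"),
        ],
    )
    def test_all_codons(self, conversion, gene_strand, ref_base, alt_base):
        checked = 0
        for codon, pos in itertools.product(CODON_LIST, range(3)):
            expected = _expected_single_sub(codon, pos, ref_base, alt_base)
            if expected is None:
                continue  # this chemistry cannot touch that base
            outcomes = run_single_edit(codon, pos, "+", gene_strand, conversion)
            relevant = [o for o in outcomes if o.codon_index == 1]
            alt, ref_aa, alt_aa = expected
            assert len(relevant) == 1
            o = relevant[0]
            assert o.alt_codon == alt
            assert o.ref_aa == ref_aa
            assert o.alt_aa == alt_aa
            checked += 1
        assert checked == 48  # 64 codons x 3 positions, a quarter carry the base

    def test_stop_gain_set_c_to_t_coding(self):
        gains = set()
        for codon, pos in itertools.product(CODON_LIST, range(3)):
            if codon[pos] != "C" or CODON_TABLE_LOCAL[codon] == "*":
                continue
            outcomes = run_single_edit(codon, pos, "+", "+", Conversion.C_TO_T)
            for o in outcomes:
                if o.codon_index == 1 and o.is_stop_gain:
                    gains.add((codon, o.alt_codon))
        assert gains == {("CAA", "TAA"), ("CAG", "TAG"), ("CGA", "TGA")}

    def test_stop_gain_set_g_to_a_template(self):
        # CDS on the opposite strand: coding G -> A; brute-force oracle
        expected = set()
        for codon, pos in itertools.product(CODON_LIST, range(3)):
            if codon[pos] != "G" or CODON_TABLE_LOCAL[codon] == "*":
                continue
            alt = codon[:pos] + "A" + codon[pos + 1 :]
            if CODON_TABLE_LOCAL[alt] == "*":
                expected.add((codon, alt))
        got = set()
        for codon, pos in itertools.product(CODON_LIST, range(3)):
            if codon[pos] != "G" or CODON_TABLE_LOCAL[codon] == "*":
                continue
            for o in run_single_edit(codon, pos, "+", "-", Conversion.C_TO_T):
                if o.codon_index == 1 and o.is_stop_gain:
                    got.add((o.ref_codon, o.alt_codon))
        assert got == expected
        assert ("TGG", "TAG") in got and ("TGG", "TGA") in got


class TestSimultaneity:
    def test_joint_edit_covers_all_singles(self, planted_builder):
        records, _ = planted_builder.finalize()
        from bescan.genome_io import TargetRegion
        from bescan.reporting import design_guides

        region = TargetRegion(records[0].contig_id, 0, records[0].length)
        guides = design_guides(records, region)
        checked = 0
        for guide in guides:
            if len(guide.editable_positions) < 2:
                continue
            joint_codons = {
                (o.feature_ref, o.codon_index) for o in guide.outcomes
            }
            for pos in guide.editable_positions:
                single = AnnotatedGuide(
                    guide.candidate, guide.window_start, guide.window_end
                )
                single.editable_positions = [pos]
                single_codons = {
                    (o.feature_ref, o.codon_index)
                    for o in simulate_edits(single, records)
                }
                assert single_codons <= joint_codons
                checked += 1
        assert checked > 0


def test_annotate_guide_strand_consistency(planted_builder):
    from bescan.genome_io import TargetRegion
    from bescan.reporting import design_guides
    from bescan.synthetic import mirror_records

    records, _ = planted_builder.finalize()
    n = records[0].length
    region = TargetRegion(records[0].contig_id, 0, n)
    fwd = design_guides(records, region)
    rev = design_guides(mirror_records(records), region)

    def outcome_sig(g):
        return tuple(
            sorted((o.ref_codon, o.alt_codon, o.codon_index) for o in g.outcomes)
        )

    fwd_map = {
        (g.candidate.strand, g.candidate.pam_start): outcome_sig(g) for g in fwd
    }
    rev_map = {
        (
            "+" if g.candidate.strand == "-" else "-",
            n - g.candidate.pam_end,
        ): outcome_sig(g)
        for g in rev
    }
    assert fwd_map == rev_map
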