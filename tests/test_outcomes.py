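import pytest

from spliceko.gene_model import revcomp
from spliceko.guide_design import (
    BaseEditorProfile,
    find_pmstop_guides,
    find_splice_guides,
)
from spliceko.outcomes import (
    classify_outcome,
    enumerate_outcomes,
    summarize_candidate,
)
from spliceko.synthetic import (
    PlantedPmStop,
    PlantedSpliceGuide,
    SyntheticLocusSpec,
    make_synthetic_locus,
)
from test_guide_design import _dummy_candidate


def _classified(candidates, t, profile):
    for c in candidates:
        outs = enumerate_outcomes(c, profile)
        for o in outs:
            classify_outcome(o, t)
        yield c, outs


class TestEnumeration:
    def test_outcome_count_is_four_to_the_m(self, profile):
        for m in (0, 1, 2, 3):
            c = _dummy_candidate(list(range(4, 4 + m)) or [4])
            c.window_cs = list(range(4, 4 + m))
            c.sense_index = {p: p - 1 for p in range(1, 21)}
            c.local_sense_seq = "C" * 20
            assert len(enumerate_outcomes(c, profile)) == 4**m

    def test_zero_window_cs_gives_single_unchanged_outcome(self, profile):
        c = _dummy_candidate([4])
        c.window_cs = []
        outs = enumerate_outcomes(c, profile)
        assert len(outs) == 1
        assert outs[0].assignment == {}

    def test_enumeration_has_no_duplicates(self, planted_locus, profile):
        for c in find_splice_guides(planted_locus.transcript, planted_locus.genome, profile):
            outs = enumerate_outcomes(c, profile)
            labels = [o.assignment_string for o in outs]
            assert len(labels) == len(set(labels))

    def test_combinatorial_guard_beyond_eight_cs(self, profile):
        c = _dummy_candidate([4])
        c.window_cs = list(range(1, 10))
        c.local_sense_seq = "C" * 20
        c.sense_index = {p: p - 1 for p in range(1, 21)}
        with pytest.raises(ValueError, match="sample"):
            enumerate_outcomes(c, profile)

    def test_toy_donor_outcomes_read_gt_at_ct_tt_at_junction(self, toy_locus, profile):
        g, t = toy_locus
        (c,) = find_splice_guides(t, g, profile)
        outs = enumerate_outcomes(c, profile)
        i0, i1 = c.dinuc_sense_idx
        dinucs = {o.edited_local_sense[i0 : i1 + 1] for o in outs}
        assert dinucs == {"GT", "AT", "CT", "TT"}

    def test_sense_reconstruction_complement_round_trip(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        for c in find_splice_guides(t, g, profile):
            for o in enumerate_outcomes(c, profile):
                assert revcomp(revcomp(o.edited_local_sense)) == o.edited_local_sense


class TestClassification:
    def test_every_critical_conversion_loses_the_splice_site(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        for c, outs in _classified(find_splice_guides(t, g, profile), t, profile):
            for o in outs:
                if o.critical_edited():
                    assert o.consequence in {"splice_donor_lost", "splice_acceptor_lost"}

    def test_all_unchanged_outcome_is_none(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        for c, outs in _classified(find_splice_guides(t, g, profile), t, profile):
            unchanged = [o for o in outs if not o.assignment]
            assert all(o.consequence == "none" for o in unchanged)

    def test_donor_loss_predicts_intron_retention_nmd(self, toy_locus, profile):
        g, t = toy_locus
        (c,) = find_splice_guides(t, g, profile)
        for o in enumerate_outcomes(c, profile):
            classify_outcome(o, t)
            if o.critical_edited():
                assert o.transcript_effect == "intron_retention_nmd"

    def test_acceptor_loss_predicts_exon_skipping(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        accs = [
            c
            for c in find_splice_guides(t, g, profile)
            if c.design_class == "splice_acceptor"
        ]
        for c, outs in _classified(accs, t, profile):
            for o in outs:
                if o.critical_edited():
                    assert o.consequence == "splice_acceptor_lost"
                    assert o.transcript_effect == "exon_skipping"

    def test_caa_codon_edits_classify_stop_and_missense(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        (c,) = [x for x in find_pmstop_guides(t, g, profile) if x.codon_ref == "CAA"]
        by_codon = {}
        for o in enumerate_outcomes(c, profile):
            classify_outcome(o, t)
            crit = c.critical_positions[0]
            if list(o.assignment) == [crit]:
                by_codon[o.assignment[crit]] = o.consequence
        assert by_codon["T"] == "pmstop"  # CAA -> TAA
        assert by_codon["G"] == "missense"  # CAA -> GAA (Glu)
        assert by_codon["A"] == "missense"  # CAA -> AAA (Lys)

    def test_nontarget_only_flag(self, toy_locus, profile):
        g, t = toy_locus
        (c,) = find_splice_guides(t, g, profile)
        for o in enumerate_outcomes(c, profile):
            classify_outcome(o, t)
            expected = bool(o.assignment) and all(b != "T" for b in o.assignment.values())
            assert ("nontarget_only" in o.flags) == expected

    def test_terminal_exon_acceptor_is_flagged(self, profile):
        spec = SyntheticLocusSpec(
            seed=23, n_exons=2, planted_guides=(PlantedSpliceGuide("acceptor", 1),)
        )
        loc = make_synthetic_locus(spec)
        (c,) = find_splice_guides(loc.transcript, loc.genome, profile)
        assert "noncoding_or_terminal_exon" in c.flags

    def test_in_frame_exon_skip_is_flagged(self, profile):
        # middle exon of fixed length 72 (divisible by 3)
        spec = SyntheticLocusSpec(
            seed=29,
            n_exons=3,
            exon_length=(72, 72),
            planted_guides=(PlantedSpliceGuide("acceptor", 1),),
        )
        loc = make_synthetic_locus(spec)
        (c,) = find_splice_guides(loc.transcript, loc.genome, profile)
        for o in enumerate_outcomes(c, profile):
            classify_outcome(o, loc.transcript)
            if o.consequence == "splice_acceptor_lost":
                assert "in_frame_skip" in o.flags


class TestSummary:
    def test_splice_candidates_are_always_knockout(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        for c, outs in _classified(find_splice_guides(t, g, profile), t, profile):
            s = summarize_candidate(c, outs)
            assert s.knockout_fraction == 1.0

    def test_caa_candidate_one_third_stop_over_single_edits(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        # restrict to the critical C so the 3 edited outcomes are TAA/GAA/AAA
        single = [x for x in find_pmstop_guides(t, g, profile) if x.codon_ref == "CAA"][0]
        outs = [
            classify_outcome(o, t)
            for o in enumerate_outcomes(single, profile)
            if set(o.assignment) <= {single.critical_positions[0]}
        ]
        s = summarize_candidate(single, outs)
        assert s.n_critical_edited == 3
        assert s.knockout_fraction == pytest.approx(1 / 3)
        assert s.missense_fraction == pytest.approx(2 / 3)

    def test_zero_window_cs_summary_carries_warning(self, profile):
        c = _dummy_candidate([4])
        c.window_cs = []
        outs = enumerate_outcomes(c, profile)
        s = summarize_candidate(c, outs)
        assert s.knockout_fraction is None
        assert s.warning
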