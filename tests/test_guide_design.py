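import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_pmstop_guides, brute_splice_guides, random_locus_spec
from spliceko.gene_model import TranscriptModel, load_genome
from spliceko.guide_design import (
    BaseEditorProfile,
    GuideCandidate,
    find_pmstop_guides,
    find_splice_guides,
    rank_guides,
    score_guide,
)
from spliceko.synthetic import (
    PlantedPmStop,
    PlantedSpliceGuide,
    SyntheticLocusSpec,
    make_synthetic_locus,
)
from conftest import TOY_SEQ


class TestProfile:
    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            BaseEditorProfile(window_start=0)
        with pytest.raises(ValueError):
            BaseEditorProfile(window_start=9, window_end=8)

    def test_pam_must_be_iupac(self):
        with pytest.raises(ValueError):
            BaseEditorProfile(pam="NQG")
        with pytest.raises(ValueError):
            BaseEditorProfile(pam="")


class TestSpliceFinder:
    def test_toy_locus_yields_exactly_the_hand_derived_candidate(self, toy_locus, profile):
        g, t = toy_locus
        cands = find_splice_guides(t, g, profile)
        assert len(cands) == 1
        c = cands[0]
        assert c.protospacer == "ACTTACTGTGAAGTCAGATC"
        assert c.pam_observed == "TGG"
        assert c.strand == "antisense"
        assert c.critical_positions == [6]
        assert c.design_class == "splice_donor"

    def test_mutated_pam_anchor_gives_no_candidates(self, profile):
        seq = TOY_SEQ[:13] + "AA" + TOY_SEQ[15:]  # destroy the sense CC anchor
        g = load_genome(io.StringIO(f">chr1\n{seq}\n"))
        t = TranscriptModel("T1", "G1", "chr1", "+", [(0, 30), (36, 45)])
        assert find_splice_guides(t, g, profile) == []

    def test_relaxed_pam_yields_superset(self, toy_locus):
        g, t = toy_locus
        ngg = {c.protospacer for c in find_splice_guides(t, g, BaseEditorProfile())}
        ng = {c.protospacer for c in find_splice_guides(t, g, BaseEditorProfile(pam="NG"))}
        assert ngg <= ng

    def test_transcript_without_canonical_sites_returns_empty(self):
        spec = SyntheticLocusSpec(
            seed=13, n_exons=2, noncanonical_donors=(1,), noncanonical_acceptors=(1,)
        )
        loc = make_synthetic_locus(spec)
        assert find_splice_guides(loc.transcript, loc.genome) == []

    def test_n_run_disqualifies_overlapping_protospacers(self):
        # N-run placed mid-intron does not remove the planted exon-side guides
        spec = SyntheticLocusSpec(
            seed=21,
            n_exons=2,
            intron_length=(90, 110),
            planted_guides=(PlantedSpliceGuide("donor", 1),),
            n_run=(1, 12),
        )
        loc = make_synthetic_locus(spec)
        cands = find_splice_guides(loc.transcript, loc.genome)
        assert len(cands) == 1
        assert "N" not in cands[0].protospacer

    def test_widening_window_never_removes_candidates(self, planted_locus):
        narrow = BaseEditorProfile(window_start=5, window_end=7)
        wide = BaseEditorProfile(window_start=4, window_end=8)
        key = lambda cs: {(c.protospacer, c.start) for c in cs}
        t, g = planted_locus.transcript, planted_locus.genome
        assert key(find_splice_guides(t, g, narrow)) <= key(find_splice_guides(t, g, wide))

    @pytest.mark.parametrize("seed", range(8))
    def test_finder_matches_brute_force_scan(self, seed, profile):
        loc = make_synthetic_locus(random_locus_spec(seed))
        t, g = loc.transcript, loc.genome
        found = {
            (c.design_class, c.start, c.genome_strand, c.protospacer)
            for c in find_splice_guides(t, g, profile)
        }
        assert found == brute_splice_guides(t, g, profile)


class TestPmStopFinder:
    def test_planted_caa_codon_yields_taa_editing_candidate(self, planted_locus, profile):
        cands = [
            c
            for c in find_pmstop_guides(planted_locus.transcript, planted_locus.genome, profile)
            if c.codon_ref == "CAA"
        ]
        assert len(cands) == 1
        c = cands[0]
        assert c.strand == "sense"
        assert c.critical_positions == [6]
        assert c.protospacer[5] == "C"  # the editable C of CAA at window position 6

    def test_tgg_codon_with_both_gs_in_window_has_two_critical_positions(
        self, planted_locus, profile
    ):
        cands = [
            c
            for c in find_pmstop_guides(planted_locus.transcript, planted_locus.genome, profile)
            if c.codon_ref == "TGG"
        ]
        assert len(cands) == 1
        assert cands[0].strand == "antisense"
        assert cands[0].critical_positions == [5, 6]

    def test_locus_without_editable_codons_in_window_returns_empty(self):
        loc = make_synthetic_locus(SyntheticLocusSpec(seed=17, n_exons=2))
        assert find_pmstop_guides(loc.transcript, loc.genome) == []

    def test_missing_cds_is_an_error(self):
        loc = make_synthetic_locus(SyntheticLocusSpec(seed=19, n_exons=2, coding=False))
        with pytest.raises(ValueError, match="no CDS"):
            find_pmstop_guides(loc.transcript, loc.genome)

    def test_frame_broken_cds_is_an_error(self, planted_locus):
        t = planted_locus.transcript
        s, e = t.cds_intervals[0]
        broken = TranscriptModel(
            t.transcript_id, t.gene_id, t.contig, t.strand, t.exons,
            [(s + 1, e)] + t.cds_intervals[1:],
        )
        with pytest.raises(ValueError, match="divisible by 3"):
            find_pmstop_guides(broken, planted_locus.genome)

    @pytest.mark.parametrize("seed", [3, 11, 30, 44])
    def test_finder_matches_brute_force_scan(self, seed, profile):
        loc = make_synthetic_locus(random_locus_spec(seed))
        t, g = loc.transcript, loc.genome
        found = {
            (c.design_class, c.start, c.genome_strand, int(c.target_id.rsplit(":", 1)[1]))
            for c in find_pmstop_guides(t, g, profile)
        }
        assert found == brute_pmstop_guides(t, g, profile)


def _dummy_candidate(critical, offset=0):
    return GuideCandidate(
        protospacer="C" * 20,
        pam_observed="AGG",
        strand="sense",
        genome_strand="+",
        contig="c",
        start=0,
        end=20,
        design_class="pmstop",
        transcript_id="t",
        target_id="t:codon:0",
        critical_positions=list(critical),
        window_cs=list(critical),
        target_spliced_offset=offset,
    )


class TestScoring:
    def setup_method(self):
        self.t = TranscriptModel("t", "g", "c", "+", [(0, 100)])
        self.profile = BaseEditorProfile()

    @pytest.mark.parametrize(
        "pos,expected", [(6, 1.0), (4, 0.5), (8, 0.5), (5, 0.75), (7, 0.75)]
    )
    def test_window_score_from_critical_position(self, pos, expected):
        c = score_guide(_dummy_candidate([pos]), self.t, self.profile)
        assert c.window_score == pytest.approx(expected)

    def test_transcript_score_is_one_at_five_prime_end(self):
        c = score_guide(_dummy_candidate([6], offset=0), self.t, self.profile)
        assert c.transcript_score == 1.0

    def test_combined_score_weighted_sum(self):
        c = score_guide(_dummy_candidate([4], offset=50), self.t, self.profile)
        assert c.combined_score == pytest.approx(0.7 * 0.5 + 0.3 * 0.5)

    @given(
        pos=st.integers(min_value=4, max_value=8),
        offset=st.integers(min_value=0, max_value=99),
    )
    @settings(deadline=None, max_examples=50)
    def test_all_scores_within_unit_interval(self, pos, offset):
        c = score_guide(_dummy_candidate([pos], offset=offset), self.t, self.profile)
        assert 0.0 <= c.window_score <= 1.0
        assert 0.0 <= c.transcript_score <= 1.0
        assert 0.0 <= c.combined_score <= 1.0

    def test_mean_of_multiple_critical_positions(self):
        c = score_guide(_dummy_candidate([5, 7]), self.t, self.profile)
        assert c.window_score == pytest.approx(1.0)  # mean 6 = midpoint


class TestRanking:
    def _scored(self, combined, window, offset, proto):
        c = _dummy_candidate([6], offset=offset)
        c.protospacer = proto
        c.combined_score, c.window_score, c.transcript_score = combined, window, 0.0
        return c

    def test_ties_broken_by_window_score(self):
        a = self._scored(0.8, 0.9, 0, "A" * 20)
        b = self._scored(0.8, 1.0, 0, "C" * 20)
        assert rank_guides([a, b]) == [b, a]

    def test_empty_input_gives_empty_output(self):
        assert rank_guides([]) == []

    def test_unscored_candidates_rejected(self):
        with pytest.raises(ValueError, match="scored"):
            rank_guides([_dummy_candidate([6])])

    def test_order_independent_of_input_order(self, planted_locus, profile):
        t, g = planted_locus.transcript, planted_locus.genome
        cands = find_splice_guides(t, g, profile) + find_pmstop_guides(t, g, profile)
        for c in cands:
            score_guide(c, t, profile)
        ranked = rank_guides(cands)
        shuffled = cands[:]
        random.Random(0).shuffle(shuffled)
        assert [c.candidate_id for c in rank_guides(shuffled)] == [
            c.candidate_id for c in ranked
        ]
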