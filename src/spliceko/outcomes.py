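"""Exhaustive enumeration and classification of base-editing outcomes.

Cytosine base editors convert every efficiently-deaminated C in the
editing window, but not always to T: C->A and C->G byproducts occur at
appreciable rates.  For a candidate with m window cytosines this module
enumerates all 4^m joint assignments (T, A, G or unchanged per C) and
classifies each outcome's functional consequence:

* splice-class guides: the junction motif is re-read from the edited
  sense sequence; any conversion of the critical C removes the invariant
  G, so *every* edited outcome at that base is a splice loss.  Donor loss
  predicts intron retention followed by nonsense-mediated decay; acceptor
  loss predicts skipping of the downstream exon.
* pmSTOP guides: the edited target codon is translated; a stop is a
  truncating knockout, a changed amino acid a missense, an unchanged one
  silent.

Acceptor guides on terminal or noncoding exons carry the
``noncoding_or_terminal_exon`` flag (splice loss there need not abolish
the protein), and in-frame exon skips are flagged ``in_frame_skip``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .gene_model import TranscriptModel
from .guide_design import BaseEditorProfile, GuideCandidate

__all__ = [
    "EditOutcome",
    "enumerate_outcomes",
    "classify_outcome",
    "summarize_candidate",
    "MAX_WINDOW_CS",
]

#: combinatorial guard: 4^m outcomes beyond m = 8 are not enumerated
MAX_WINDOW_CS = 8

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

KNOCKOUT_CONSEQUENCES = {"splice_donor_lost", "splice_acceptor_lost", "pmstop"}


@dataclass
class EditOutcome:
    """One joint assignment of conversions to a candidate's window cytosines.

    ``assignment`` maps edited protospacer positions to their new base on
    the protospacer strand (positions absent from the map are unchanged).
    """

    candidate: GuideCandidate
    assignment: dict[int, str]
    edited_protospacer: str
    edited_local_sense: str
    consequence: str = "none"
    transcript_effect: str = "none"
    flags: set = field(default_factory=set)

    @property
    def candidate_id(self) -> str:
        return self.candidate.candidate_id

    @property
    def assignment_string(self) -> str:
        """Compact label, e.g. ``"6T"`` or ``"4A;6T"`` (empty = unchanged)."""
        return ";".join(f"{p}{b}" for p, b in sorted(self.assignment.items()))

    def critical_edited(self) -> bool:
        return any(p in self.assignment for p in self.candidate.critical_positions)


def enumerate_outcomes(
    c: GuideCandidate, profile: BaseEditorProfile | None = None
) -> list[EditOutcome]:
    """All 4^m outcomes over the candidate's m window cytosines.

    The all-unchanged outcome is included.  m > 8 raises, advising a
    sampling approach instead of exhaustive enumeration.
    """
    profile = profile or BaseEditorProfile()
    positions = list(c.window_cs)
    m = len(positions)
    if m > MAX_WINDOW_CS:
        raise ValueError(
            f"candidate has {m} window cytosines (> {MAX_WINDOW_CS}); 4^{m} outcomes "
            "are too many to enumerate — sample assignments instead"
        )
    options = (None,) + tuple(profile.conversions)
    outcomes = []
    for combo in itertools.product(options, repeat=m):
        assignment = {p: b for p, b in zip(positions, combo) if b is not None}
        outcomes.append(_build_outcome(c, assignment))
    return outcomes


def _build_outcome(c: GuideCandidate, assignment: dict[int, str]) -> EditOutcome:
    proto = list(c.protospacer)
    sense = list(c.local_sense_seq)
    for p, b in assignment.items():
        if c.protospacer[p - 1] != "C":
            raise ValueError(f"position {p} of {c.candidate_id} is not a C")
        proto[p - 1] = b
        j = c.sense_index.get(p)
        if j is not None:
            # edit is on the protospacer strand; project onto the sense strand
            sense[j] = b if c.strand == "sense" else _COMP[b]
    return EditOutcome(
        candidate=c,
        assignment=assignment,
        edited_protospacer="".join(proto),
        edited_local_sense="".join(sense),
    )


def classify_outcome(o: EditOutcome, t: TranscriptModel) -> EditOutcome:
    """Assign consequence, predicted transcript effect and flags."""
    c = o.candidate
    o.flags |= set(c.flags)
    if o.assignment and all(b != "T" for b in o.assignment.values()):
        o.flags.add("nontarget_only")

    if c.design_class in {"splice_donor", "splice_acceptor"}:
        i0, i1 = c.dinuc_sense_idx
        dinuc = o.edited_local_sense[i0 : i1 + 1]
        intact = dinuc == ("GT" if c.design_class == "splice_donor" else "AG")
        if intact:
            o.consequence = "none"
            o.transcript_effect = "none"
        elif c.design_class == "splice_donor":
            o.consequence = "splice_donor_lost"
            o.transcript_effect = "intron_retention_nmd"
        else:
            o.consequence = "splice_acceptor_lost"
            o.transcript_effect = "exon_skipping"
            if c.skipped_exon_len is not None and c.skipped_exon_len % 3 == 0:
                o.flags.add("in_frame_skip")
    elif c.design_class == "pmstop":
        codon = _edited_codon(o)
        if codon == c.codon_ref:
            # C->T/A/G always changes the base, so an identical codon means
            # no edit touched it
            o.consequence = "none"
            o.transcript_effect = "none"
        else:
            aa_ref = str(Seq(c.codon_ref).translate())
            aa_new = str(Seq(codon).translate())
            if aa_new == "*":
                o.consequence = "pmstop"
                o.transcript_effect = "truncation"
            elif aa_new != aa_ref:
                o.consequence = "missense"
                o.transcript_effect = "none"
            else:
                o.consequence = "silent"
                o.transcript_effect = "none"
    else:
        raise ValueError(f"unknown design class {c.design_class!r}")
    return o


def _edited_codon(o: EditOutcome) -> str:
    c = o.candidate
    codon = []
    for pos, j in enumerate(c.codon_sense_idx):
        codon.append(c.codon_ref[pos] if j is None else o.edited_local_sense[j])
    return "".join(codon)


@dataclass
class CandidateSummary:
    """Knockout / missense / silent fractions over critical-edited outcomes."""

    candidate_id: str
    design_class: str
    n_outcomes: int
    n_critical_edited: int
    knockout_fraction: float | None
    missense_fraction: float | None
    silent_fraction: float | None
    flags: set
    warning: str = ""


def summarize_candidate(
    c: GuideCandidate, outcomes: list[EditOutcome]
) -> CandidateSummary:
    """Decision-support summary over outcomes where a critical C is edited."""
    edited = [o for o in outcomes if o.critical_edited()]
    flags = set(c.flags)
    for o in outcomes:
        flags |= o.flags
    if not c.window_cs or not edited:
        return CandidateSummary(
            candidate_id=c.candidate_id,
            design_class=c.design_class,
            n_outcomes=len(outcomes),
            n_critical_edited=0,
            knockout_fraction=None,
            missense_fraction=None,
            silent_fraction=None,
            flags=flags,
            warning="no editable window cytosines" if not c.window_cs else "no critical edits",
        )
    n = len(edited)
    ko = sum(o.consequence in KNOCKOUT_CONSEQUENCES for o in edited)
    mis = sum(o.consequence == "missense" for o in edited)
    sil = sum(o.consequence == "silent" for o in edited)
    return CandidateSummary(
        candidate_id=c.candidate_id,
        design_class=c.design_class,
        n_outcomes=len(outcomes),
        n_critical_edited=n,
        knockout_fraction=ko / n,
        missense_fraction=mis / n,
        silent_fraction=sil / n,
        flags=flags,
    )
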