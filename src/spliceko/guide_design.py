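"""Design of knockout sgRNAs for cytosine base editors.

Two design classes are produced:

* **Splice-disrupting guides** (``splice_donor`` / ``splice_acceptor``):
  for every canonical GT donor or AG acceptor of a transcript, the region
  around the junction is extracted and the pattern N20-PAM is matched to
  the *antisense* strand of that region.  A match is a candidate when the
  editing window (protospacer positions ``window_start..window_end``,
  position 1 = PAM-distal 5' end) covers the critical cytosine — the
  antisense base paired with the invariant G of GT/AG.  Converting that C
  (to T, or via nontarget editing to A or G) destroys the motif.

* **pmSTOP guides** (``pmstop``): guides whose in-window C->T edit turns a
  codon into a premature stop.  On the sense strand the editable codons
  are CAA->TAA, CAG->TAG and CGA->TGA; TGG codons are reachable from the
  antisense strand, where the Cs paired with either G convert TGG to
  TAG/TGA (or TAA when both edit).

Scoring combines a window score (how close the critical C sits to the
centre of the editing window, where deamination is most efficient) and a
transcript score (how early in the spliced transcript the lesion falls);
both are in [0, 1] and combined with configurable weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from statistics import mean

from Bio.Data.IUPACData import ambiguous_dna_values

from .gene_model import (
    GenomeSequence,
    SpliceSite,
    TranscriptModel,
    extract_splice_sites,
    revcomp,
)

__all__ = [
    "BaseEditorProfile",
    "GuideCandidate",
    "find_splice_guides",
    "find_pmstop_guides",
    "score_guide",
    "rank_guides",
    "iupac_match",
]

PROTOSPACER_LEN = 20

#: sense-strand codons one C->T edit away from a stop, mapping codon ->
#: index of the editable C within the codon
SENSE_STOP_CODONS = {"CAA": 0, "CAG": 0, "CGA": 0}
#: codon reachable via antisense editing: either G of TGG pairs with an
#: antisense C whose edit yields TAG (pos 1), TGA (pos 2) or TAA (both)
ANTISENSE_STOP_CODON = "TGG"

STOP_CODONS = {"TAA", "TAG", "TGA"}


def iupac_match(seq: str, pattern: str) -> bool:
    """True when every concrete base of ``seq`` is admitted by the IUPAC ``pattern``."""
    if len(seq) != len(pattern):
        return False
    return all(
        base in ambiguous_dna_values.get(code, "") for base, code in zip(seq, pattern)
    )


@dataclass
class BaseEditorProfile:
    """PAM and editing-window description of one cytosine base editor.

    ``window_start``/``window_end`` are protospacer positions with 1 at the
    PAM-distal 5' end; the default 4-8 window is where BE3/BE4 deamination
    is most efficient.  ``target_conversion`` is the intended edit and
    ``nontarget_conversions`` the editor's known byproducts.
    """

    name: str = "BE4"
    pam: str = "NGG"
    window_start: int = 4
    window_end: int = 8
    target_conversion: str = "T"
    nontarget_conversions: tuple[str, ...] = ("A", "G")

    def __post_init__(self) -> None:
        if not (1 <= self.window_start <= self.window_end <= PROTOSPACER_LEN):
            raise ValueError(
                f"editing window [{self.window_start},{self.window_end}] must satisfy "
                f"1 <= start <= end <= {PROTOSPACER_LEN}"
            )
        if not self.pam or any(c not in ambiguous_dna_values for c in self.pam):
            raise ValueError(f"PAM must be a non-empty IUPAC string, got {self.pam!r}")

    @property
    def conversions(self) -> tuple[str, ...]:
        return (self.target_conversion,) + tuple(self.nontarget_conversions)

    def window_positions(self) -> range:
        return range(self.window_start, self.window_end + 1)


@dataclass
class GuideCandidate:
    """A 20-nt protospacer + PAM with its design class and edit bookkeeping.

    ``strand`` is relative to the pre-mRNA sense strand; ``genome_strand``
    is the plus/minus strand of the genome the protospacer is read from.
    ``start``/``end`` give the plus-strand footprint of the protospacer
    (the PAM lies immediately 3' of it on ``genome_strand``).

    ``critical_positions`` are the protospacer positions whose C edit
    confers knockout; ``window_cs`` every in-window protospacer C.  The
    ``sense_index`` map and the local sense context let the outcome model
    reconstruct edited sense-strand sequence without genome access.
    """

    protospacer: str
    pam_observed: str
    strand: str  # "sense" | "antisense"
    genome_strand: str  # "+" | "-"
    contig: str
    start: int
    end: int
    design_class: str  # "splice_donor" | "splice_acceptor" | "pmstop"
    transcript_id: str
    target_id: str
    critical_positions: list[int]
    window_cs: list[int]
    target_spliced_offset: int
    # local sense-strand context (pre-mRNA orientation)
    local_sense_seq: str = ""
    sense_index: dict[int, int] = field(default_factory=dict)  # protospacer pos -> index
    dinuc_sense_idx: tuple[int, int] | None = None
    ref_dinucleotide: str = ""
    codon_ref: str = ""
    codon_sense_idx: tuple = ()  # per codon position: sense index or None
    skipped_exon_len: int | None = None
    flags: set = field(default_factory=set)
    window_score: float | None = None
    transcript_score: float | None = None
    combined_score: float | None = None

    @property
    def candidate_id(self) -> str:
        return (
            f"{self.transcript_id}|{self.design_class}|{self.contig}:"
            f"{self.start}-{self.end}({self.genome_strand})"
        )


def _scan_antisense(
    sense_seq: str,
    critical_sense_indices: list[int],
    profile: BaseEditorProfile,
) -> list[tuple[int, str, str, list[int], list[int]]]:
    """Scan the antisense strand of a sense-oriented region for candidates.

    Returns tuples (i, protospacer, pam, critical_positions, window_cs)
    where i is the protospacer start index on the antisense string and
    positions are 1-based protospacer positions.  A placement qualifies
    when at least one critical index lands in the editing window with a C
    on the antisense strand, the PAM matches, and no N is overlapped.
    """
    anti = revcomp(sense_seq)
    L = len(anti)
    plen = len(profile.pam)
    crit_anti = [L - 1 - j for j in critical_sense_indices]
    out = []
    for i in range(0, L - PROTOSPACER_LEN - plen + 1):
        proto = anti[i : i + PROTOSPACER_LEN]
        pam = anti[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + plen]
        crits = []
        for a in crit_anti:
            p = a - i + 1
            if profile.window_start <= p <= profile.window_end and proto[p - 1] == "C":
                crits.append(p)
        if not crits:
            continue
        if not iupac_match(pam, profile.pam):
            continue
        if "N" in proto or "N" in pam:
            continue
        window_cs = [
            p for p in profile.window_positions() if p <= PROTOSPACER_LEN and proto[p - 1] == "C"
        ]
        out.append((i, proto, pam, sorted(crits), window_cs))
    return out


def find_splice_guides(
    t: TranscriptModel,
    genome: GenomeSequence,
    profile: BaseEditorProfile | None = None,
    flank: int = 30,
    *,
    include_noncanonical: bool = False,
) -> list[GuideCandidate]:
    """All splice-disrupting candidates of a transcript.

    For every canonical splice site (non-canonical sites are skipped unless
    ``include_noncanonical``), every antisense protospacer+PAM whose editing
    window contains the critical C is returned.  Transcripts without
    canonical sites yield an empty list.
    """
    if flank < 20:
        raise ValueError(f"flank must be >= 20 nt, got {flank}")
    profile = profile or BaseEditorProfile()
    candidates: list[GuideCandidate] = []
    n_contig = genome.length(t.contig)
    for site in extract_splice_sites(t, genome):
        if not site.canonical and not include_noncanonical:
            continue
        # candidates exist only when the sense base is G (antisense C)
        sense_g_idx = 0 if site.kind == "donor" else 1
        if site.dinucleotide[sense_g_idx] != "G":
            continue
        # extraction is clamped at contig ends: placements that would need
        # missing sequence simply cannot exist
        wstart = max(0, site.dinuc_plus_start - flank)
        wend = min(n_contig, site.dinuc_plus_start + 2 + flank)
        S = genome.fetch(t.contig, wstart, wend)
        if t.strand == "-":
            S = revcomp(S)
        L = len(S)
        crit_sense_idx = _sense_idx_of_plus(site.critical_c_coord, t.strand, wstart, wend)
        dinuc_g_idx = crit_sense_idx
        for i, proto, pam, crits, window_cs in _scan_antisense(S, [crit_sense_idx], profile):
            # map antisense indices back to plus-strand coordinates
            if t.strand == "+":
                start = wstart + L - PROTOSPACER_LEN - i
                genome_strand = "-"
            else:
                start = wstart + i
                genome_strand = "+"
            sense_index = {p: L - 1 - (i + p - 1) for p in range(1, PROTOSPACER_LEN + 1)}
            cand = GuideCandidate(
                protospacer=proto,
                pam_observed=pam,
                strand="antisense",
                genome_strand=genome_strand,
                contig=t.contig,
                start=start,
                end=start + PROTOSPACER_LEN,
                design_class="splice_donor" if site.kind == "donor" else "splice_acceptor",
                transcript_id=t.transcript_id,
                target_id=site.site_id,
                critical_positions=crits,
                window_cs=window_cs,
                target_spliced_offset=site.spliced_offset,
                local_sense_seq=S,
                sense_index=sense_index,
                dinuc_sense_idx=(
                    (dinuc_g_idx, dinuc_g_idx + 1)
                    if site.kind == "donor"
                    else (dinuc_g_idx - 1, dinuc_g_idx)
                ),
                ref_dinucleotide=site.dinucleotide,
            )
            if site.kind == "acceptor":
                ei = site.downstream_exon_index
                es, ee = t.exons[ei]
                cand.skipped_exon_len = ee - es
                terminal = ei == t.n_exons - 1
                noncoding = bool(t.cds_intervals) and not t.exon_is_coding(ei)
                if terminal or noncoding:
                    cand.flags.add("noncoding_or_terminal_exon")
            candidates.append(cand)
    return candidates


def _sense_region(
    t: TranscriptModel, genome: GenomeSequence, center: int, flank: int
) -> tuple[str, int, int]:
    """Sense-oriented sequence around a genomic coordinate, clamped to the contig.

    Returns (sense_seq, plus_start, plus_end).
    """
    n = genome.length(t.contig)
    start = max(0, center - flank)
    end = min(n, center + flank + 1)
    seq = genome.fetch(t.contig, start, end)
    if t.strand == "-":
        seq = revcomp(seq)
    return seq, start, end


def _sense_idx_of_plus(coord: int, t_strand: str, wstart: int, wend: int) -> int | None:
    if not (wstart <= coord < wend):
        return None
    return coord - wstart if t_strand == "+" else (wend - 1) - coord


def find_pmstop_guides(
    t: TranscriptModel,
    genome: GenomeSequence,
    profile: BaseEditorProfile | None = None,
    context_flank: int = 30,
) -> list[GuideCandidate]:
    """Candidates whose in-window C edit introduces a premature stop codon.

    Requires a CDS of length divisible by 3.  The terminal stop codon is
    excluded; 3'-UTR sequence is never scanned (codons come from the CDS).
    """
    profile = profile or BaseEditorProfile()
    if not t.cds_intervals:
        raise ValueError(f"transcript {t.transcript_id} has no CDS")
    cds_seq = t.cds_sequence(genome)
    if len(cds_seq) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds_seq)} of {t.transcript_id} is not divisible by 3"
        )
    coords = t.cds_coords()
    n_codons = len(cds_seq) // 3
    candidates: list[GuideCandidate] = []
    for k in range(n_codons):
        codon = cds_seq[3 * k : 3 * k + 3]
        codon_coords = coords[3 * k : 3 * k + 3]
        if codon in STOP_CODONS or k == n_codons - 1:
            continue
        if codon in SENSE_STOP_CODONS:
            candidates.extend(
                _sense_codon_candidates(t, genome, profile, k, codon, codon_coords, context_flank)
            )
        if codon == ANTISENSE_STOP_CODON:
            candidates.extend(
                _tgg_codon_candidates(t, genome, profile, k, codon, codon_coords, context_flank)
            )
    return candidates


def _codon_target_meta(
    t: TranscriptModel, k: int, codon: str, codon_coords: list[int], wstart: int, wend: int
) -> dict:
    return {
        "target_id": f"{t.transcript_id}:codon:{k}",
        "codon_ref": codon,
        "codon_sense_idx": tuple(
            _sense_idx_of_plus(c, t.strand, wstart, wend) for c in codon_coords
        ),
    }


def _sense_codon_candidates(t, genome, profile, k, codon, codon_coords, flank):
    c0 = codon_coords[SENSE_STOP_CODONS[codon]]
    W, wstart, wend = _sense_region(t, genome, c0, flank)
    crit_idx = _sense_idx_of_plus(c0, t.strand, wstart, wend)
    plen = len(profile.pam)
    out = []
    for i in range(0, len(W) - PROTOSPACER_LEN - plen + 1):
        p = crit_idx - i + 1
        if not (profile.window_start <= p <= profile.window_end):
            continue
        proto = W[i : i + PROTOSPACER_LEN]
        pam = W[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + plen]
        if proto[p - 1] != "C" or not iupac_match(pam, profile.pam):
            continue
        if "N" in proto or "N" in pam:
            continue
        window_cs = [q for q in profile.window_positions() if proto[q - 1] == "C"]
        if t.strand == "+":
            start, genome_strand = wstart + i, "+"
        else:
            start, genome_strand = wend - (i + PROTOSPACER_LEN), "-"
        cand = GuideCandidate(
            protospacer=proto,
            pam_observed=pam,
            strand="sense",
            genome_strand=genome_strand,
            contig=t.contig,
            start=start,
            end=start + PROTOSPACER_LEN,
            design_class="pmstop",
            transcript_id=t.transcript_id,
            critical_positions=[p],
            window_cs=window_cs,
            target_spliced_offset=t.spliced_offset(codon_coords[0]),
            local_sense_seq=W,
            sense_index={q: i + q - 1 for q in range(1, PROTOSPACER_LEN + 1)},
            **_codon_target_meta(t, k, codon, codon_coords, wstart, wend),
        )
        out.append(cand)
    return out


def _tgg_codon_candidates(t, genome, profile, k, codon, codon_coords, flank):
    # both Gs of TGG pair with antisense Cs; centre the region between them
    g_coords = [codon_coords[1], codon_coords[2]]
    W, wstart, wend = _sense_region(t, genome, g_coords[0], flank + 1)
    crit_sense = [_sense_idx_of_plus(c, t.strand, wstart, wend) for c in g_coords]
    crit_sense = [j for j in crit_sense if j is not None and W[j] == "G"]
    out = []
    for i, proto, pam, crits, window_cs in _scan_antisense(W, crit_sense, profile):
        L = len(W)
        if t.strand == "+":
            start = wstart + L - PROTOSPACER_LEN - i
            genome_strand = "-"
        else:
            start = wstart + i
            genome_strand = "+"
        cand = GuideCandidate(
            protospacer=proto,
            pam_observed=pam,
            strand="antisense",
            genome_strand=genome_strand,
            contig=t.contig,
            start=start,
            end=start + PROTOSPACER_LEN,
            design_class="pmstop",
            transcript_id=t.transcript_id,
            critical_positions=crits,
            window_cs=window_cs,
            target_spliced_offset=t.spliced_offset(codon_coords[0]),
            local_sense_seq=W,
            sense_index={p: L - 1 - (i + p - 1) for p in range(1, PROTOSPACER_LEN + 1)},
            **_codon_target_meta(t, k, codon, codon_coords, wstart, wend),
        )
        out.append(cand)
    return out


def score_guide(
    c: GuideCandidate,
    t: TranscriptModel,
    profile: BaseEditorProfile | None = None,
    weights: tuple[float, float] = (0.7, 0.3),
) -> GuideCandidate:
    """Attach window, transcript and combined scores (each in [0, 1]).

    window_score = max(0, 1 - |p - mid| / span) with p the critical
    position (mean when several), mid the window midpoint and span the
    window width; transcript_score = 1 - d/L with d the spliced-transcript
    offset of the target and L the spliced length; combined is the
    weighted sum, clamped to [0, 1].
    """
    profile = profile or BaseEditorProfile()
    p = mean(c.critical_positions)
    mid = (profile.window_start + profile.window_end) / 2
    span = profile.window_end - profile.window_start
    if span == 0:
        ws = 1.0 if p == mid else 0.0
    else:
        ws = max(0.0, 1.0 - abs(p - mid) / span)
    L = t.spliced_length
    ts = min(1.0, max(0.0, 1.0 - c.target_spliced_offset / L)) if L else 0.0
    w_win, w_tx = weights
    c.window_score = min(1.0, ws)
    c.transcript_score = ts
    c.combined_score = min(1.0, max(0.0, w_win * ws + w_tx * ts))
    return c


def rank_guides(cs: list[GuideCandidate]) -> list[GuideCandidate]:
    """Deterministic ranking: descending combined score; ties broken by
    higher window score, then smaller transcript offset, then protospacer."""
    if any(c.combined_score is None for c in cs):
        raise ValueError("all candidates must be scored before ranking")
    return sorted(
        cs,
        key=lambda c: (
            -c.combined_score,
            -c.window_score,
            c.target_spliced_offset,
            c.protospacer,
        ),
    )
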