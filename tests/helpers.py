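"""Independent brute-force oracles and randomized fixture specs for tests.

The oracles scan every protospacer placement on both genome strands with
direct window/PAM tests, sharing no scanning code with the package's
finders; they are the reference the finders are checked against.
"""

from __future__ import annotations

import numpy as np

from spliceko.gene_model import (
    GenomeSequence,
    TranscriptModel,
    extract_splice_sites,
    revcomp,
)
from spliceko.guide_design import BaseEditorProfile, iupac_match
from spliceko.synthetic import PlantedPmStop, PlantedSpliceGuide, SyntheticLocusSpec

STOPS = {"TAA", "TAG", "TGA"}


def _placements(plus_seq: str, pam_len: int):
    """Yield (start, genome_strand, protospacer, pam, coord_of_position)."""
    n = len(plus_seq)
    for a in range(0, n - 20 - pam_len + 1):
        proto = plus_seq[a : a + 20]
        pam = plus_seq[a + 20 : a + 20 + pam_len]
        yield a, "+", proto, pam, (lambda p, a=a: a + p - 1)
    for a in range(pam_len, n - 20 + 1):
        proto = revcomp(plus_seq[a : a + 20])
        pam = revcomp(plus_seq[a - pam_len : a])
        yield a, "-", proto, pam, (lambda p, a=a: a + 20 - p)


def brute_splice_guides(
    t: TranscriptModel, genome: GenomeSequence, profile: BaseEditorProfile
) -> set[tuple]:
    """All (class, start, genome_strand, protospacer) whose editing window
    covers a canonical site's critical C with a matching PAM."""
    plus = genome.sequence(t.contig)
    targets = []
    for s in extract_splice_sites(t, genome):
        if not s.canonical:
            continue
        cls = "splice_donor" if s.kind == "donor" else "splice_acceptor"
        targets.append((s.critical_c_coord, cls))
    out = set()
    for a, strand, proto, pam, coord_of in _placements(plus, len(profile.pam)):
        if "N" in proto or "N" in pam or not iupac_match(pam, profile.pam):
            continue
        for g, cls in targets:
            for p in range(profile.window_start, profile.window_end + 1):
                if coord_of(p) == g and proto[p - 1] == "C":
                    out.add((cls, a, strand, proto))
    return out


def brute_pmstop_guides(
    t: TranscriptModel, genome: GenomeSequence, profile: BaseEditorProfile
) -> set[tuple]:
    """All (class, start, genome_strand, codon_index) placements that can
    edit a CAA/CAG/CGA (sense) or TGG (antisense) codon to a stop."""
    plus = genome.sequence(t.contig)
    cds = t.cds_sequence(genome)
    coords = t.cds_coords()
    n_codons = len(cds) // 3
    # (coord, required genome strand of the protospacer, codon index)
    targets = []
    for k in range(n_codons - 1):  # terminal codon excluded
        codon = cds[3 * k : 3 * k + 3]
        if codon in STOPS:
            continue
        if codon in {"CAA", "CAG", "CGA"}:
            targets.append((coords[3 * k], t.strand, k))
        elif codon == "TGG":
            anti = "-" if t.strand == "+" else "+"
            targets.append((coords[3 * k + 1], anti, k))
            targets.append((coords[3 * k + 2], anti, k))
    out = set()
    for a, strand, proto, pam, coord_of in _placements(plus, len(profile.pam)):
        if "N" in proto or "N" in pam or not iupac_match(pam, profile.pam):
            continue
        for g, req_strand, k in targets:
            if strand != req_strand:
                continue
            for p in range(profile.window_start, profile.window_end + 1):
                if coord_of(p) == g and proto[p - 1] == "C":
                    out.add(("pmstop", a, strand, k))
    return out


def random_locus_spec(seed: int) -> SyntheticLocusSpec:
    """A varied but always-feasible synthetic-locus recipe."""
    rng = np.random.default_rng(seed)
    n_exons = int(rng.integers(2, 5))
    strand = "+" if rng.random() < 0.5 else "-"
    kinds = ["donor", "acceptor"]
    guides = [
        PlantedSpliceGuide(
            kind=kinds[int(rng.integers(0, 2))],
            intron_index=int(rng.integers(1, n_exons)),
            window_position=int(rng.integers(4, 9)),
        )
    ]
    pmstops = []
    if rng.random() < 0.5:
        codon = ["CAA", "CAG", "CGA", "TGG"][int(rng.integers(0, 4))]
        pmstops.append(
            PlantedPmStop(
                codon=codon,
                codon_index=int(rng.integers(2, 15)),
                window_position=int(rng.integers(4, 9)),
            )
        )
    return SyntheticLocusSpec(
        seed=seed,
        n_exons=n_exons,
        strand=strand,
        exon_length=(70, 90),
        planted_guides=tuple(guides),
        planted_pmstops=tuple(pmstops),
    )
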