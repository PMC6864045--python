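"""Genome and transcript-model input, and splice-site extraction.

Loads a (multi-record) FASTA genome and a GTF2.2 or GFF3 annotation into
simple in-memory models, then extracts every exon/intron junction of a
transcript together with the base that a cytosine base editor must convert
to destroy the site.

Coordinate convention
---------------------
All coordinates are 0-based, half-open on the forward (plus) strand of the
genome.  GTF and GFF3 coordinates (1-based, inclusive) are converted on
read.  Transcript models keep their exons in *transcript* order, i.e. for a
minus-strand gene the first exon is the genomically last interval.

Splice-site anatomy
-------------------
A canonical intron starts with the donor dinucleotide ``GT`` and ends with
the acceptor dinucleotide ``AG``, read on the pre-mRNA sense strand.  The
invariant ``G`` of either motif pairs with a cytosine on the opposite
strand; converting that cytosine (C->T, or the editor's nontarget C->A/G)
removes the motif and abolishes splicing.  ``SpliceSite.critical_c_coord``
records the genomic position of the invariant G — the editable C sits on
the opposite strand at the same position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "SpliceSite",
    "SpliceWindow",
    "load_genome",
    "write_genome",
    "load_transcripts",
    "extract_splice_sites",
    "splice_window",
    "revcomp",
    "MIN_FLANK",
]

#: IUPAC nucleotide alphabet accepted in genome input.
IUPAC_DNA = set("ACGTNRYSWKMBDHV")

#: Minimum extraction flank: an antisense protospacer whose editing window
#: (positions 4-8) covers the critical C at genomic position g spans sense
#: offsets [g-19, g+7], so 20 nt per side always suffices.
MIN_FLANK = 20

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by contig name.

    Retrieval is 0-based half-open and bounds-checked.  Soft-masking
    (lowercase input) is preserved as a per-position boolean flag, never in
    the sequence itself.
    """

    def __init__(self, contigs: dict[str, str], soft_mask: dict[str, np.ndarray] | None = None):
        self._contigs = dict(contigs)
        self._soft_mask = dict(soft_mask or {})
        for name, seq in self._contigs.items():
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise ValueError(f"contig {name!r}: non-IUPAC characters {sorted(bad)}")

    @property
    def contigs(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def length(self, contig: str) -> int:
        self._check_contig(contig)
        return len(self._contigs[contig])

    def sequence(self, contig: str) -> str:
        self._check_contig(contig)
        return self._contigs[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Forward-strand subsequence over [start, end)."""
        self._check_contig(contig)
        n = len(self._contigs[contig])
        if not (0 <= start <= end <= n):
            raise IndexError(
                f"interval [{start}, {end}) outside contig {contig!r} of length {n}"
            )
        return self._contigs[contig][start:end]

    def fetch_rc(self, contig: str, start: int, end: int) -> str:
        """Reverse complement of the forward-strand subsequence."""
        return revcomp(self.fetch(contig, start, end))

    def soft_mask(self, contig: str) -> np.ndarray | None:
        """Boolean per-position soft-mask flag, or None if none present."""
        self._check_contig(contig)
        return self._soft_mask.get(contig)

    def _check_contig(self, contig: str) -> None:
        if contig not in self._contigs:
            raise KeyError(f"unknown contig {contig!r}; have {sorted(self._contigs)}")


def load_genome(path: Union[str, Path, io.TextIOBase]) -> GenomeSequence:
    """Read a multi-record FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; lowercase (soft-masked) stretches are kept as a
    per-position flag.  Duplicate record ids, empty files and non-IUPAC
    characters are rejected.
    """
    contigs: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig id {rec.id!r} in FASTA input")
            raw = str(rec.seq)
            mask = np.frombuffer(raw.encode(), dtype=np.uint8)
            lower = (mask >= ord("a")) & (mask <= ord("z"))
            if lower.any():
                masks[rec.id] = lower
            contigs[rec.id] = raw.upper()
    finally:
        if handle is not path:
            handle.close()
    if not contigs:
        raise ValueError("FASTA input contains no records")
    return GenomeSequence(contigs, masks)


def write_genome(genome: GenomeSequence, path: Union[str, Path], width: int = 60) -> None:
    """Write a genome back to FASTA, 60 columns per line, contigs in load order."""
    with open(path, "w") as fh:
        fh.write(fasta_text(genome, width))


def fasta_text(genome: GenomeSequence, width: int = 60) -> str:
    chunks = []
    for name in genome.contigs:
        seq = genome.sequence(name)
        chunks.append(f">{name}\n")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width] + "\n")
    return "".join(chunks)


@dataclass
class TranscriptModel:
    """Exon/intron structure of one transcript.

    ``exons`` and ``cds_intervals`` are genomic (plus-strand) 0-based
    half-open intervals listed in transcript (5'->3') order; for a
    minus-strand transcript they are therefore genomically descending.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        """Mature (exon-joined) transcript sequence, 5'->3'."""
        if self.strand == "+":
            return "".join(genome.fetch(self.contig, s, e) for s, e in self.exons)
        return "".join(genome.fetch_rc(self.contig, s, e) for s, e in self.exons)

    def exon_cumlens(self) -> list[int]:
        """Cumulative spliced length after each exon (transcript order)."""
        out, total = [], 0
        for s, e in self.exons:
            total += e - s
            out.append(total)
        return out

    def spliced_offset(self, coord: int) -> int:
        """Transcript (spliced) offset of a genomic coordinate inside an exon."""
        off = 0
        for s, e in self.exons:
            if s <= coord < e:
                return off + (coord - s if self.strand == "+" else e - 1 - coord)
            off += e - s
        raise ValueError(f"coordinate {coord} not exonic in {self.transcript_id}")

    def cds_coords(self) -> list[int]:
        """Genomic coordinate of every CDS base, in transcript (5'->3') order."""
        coords: list[int] = []
        for s, e in self.cds_intervals:
            if self.strand == "+":
                coords.extend(range(s, e))
            else:
                coords.extend(range(e - 1, s - 1, -1))
        return coords

    def cds_sequence(self, genome: GenomeSequence) -> str:
        if self.strand == "+":
            return "".join(genome.fetch(self.contig, s, e) for s, e in self.cds_intervals)
        return "".join(genome.fetch_rc(self.contig, s, e) for s, e in self.cds_intervals)

    def exon_is_coding(self, exon_index: int) -> bool:
        """Whether exon ``exon_index`` (0-based, transcript order) overlaps the CDS."""
        s, e = self.exons[exon_index]
        return any(cs < e and s < ce for cs, ce in self.cds_intervals)


def _transcript_order(intervals: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    return sorted(intervals, reverse=(strand == "-"))


def load_transcripts(
    path: Union[str, Path],
    genome: GenomeSequence,
    *,
    from_string: bool = False,
) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 annotation into transcript models.

    Both dialects are accepted (gffutils autodetects); exon features must
    carry a transcript identifier (``transcript_id`` attribute in GTF,
    ``Parent`` in GFF3).  Models are validated against the genome: exons
    must lie within their contig and every CDS interval inside an exon.
    """
    import gffutils

    data = str(path) if not from_string else path
    db = gffutils.create_db(
        data,
        ":memory:",
        from_string=from_string,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def parent_ids(feat) -> list[str]:
        if "transcript_id" in feat.attributes:
            return list(feat.attributes["transcript_id"])
        if "Parent" in feat.attributes:
            return list(feat.attributes["Parent"])
        raise ValueError(f"feature at {feat.seqid}:{feat.start} lacks a transcript id")

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        iv = (feat.start - 1, feat.end)  # 1-based inclusive -> 0-based half-open
        for tid in parent_ids(feat):
            info = meta.setdefault(
                tid,
                {
                    "contig": feat.seqid,
                    "strand": feat.strand,
                    "gene_id": (feat.attributes.get("gene_id") or [""])[0],
                },
            )
            if feat.strand not in {"+", "-"}:
                raise ValueError(f"unknown strand symbol {feat.strand!r} for {tid}")
            if feat.seqid != info["contig"]:
                raise ValueError(f"transcript {tid} spans multiple contigs")
            (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    models = []
    for tid in sorted(exons):
        info = meta[tid]
        contig, strand = info["contig"], info["strand"]
        if contig not in genome:
            raise ValueError(f"annotation contig {contig!r} absent from genome")
        n = genome.length(contig)
        exon_ivs = _transcript_order(exons[tid], strand)
        for s, e in exon_ivs:
            if not (0 <= s < e <= n):
                raise ValueError(f"exon [{s},{e}) of {tid} outside contig {contig!r}")
        cds_ivs = _transcript_order(cds.get(tid, []), strand)
        for cs, ce in cds_ivs:
            if not any(s <= cs and ce <= e for s, e in exon_ivs):
                raise ValueError(f"CDS [{cs},{ce}) of {tid} not contained in an exon")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"] or tid,
                contig=contig,
                strand=strand,
                exons=exon_ivs,
                cds_intervals=cds_ivs,
            )
        )
    return models


@dataclass
class SpliceSite:
    """One donor or acceptor junction of a transcript.

    ``dinucleotide`` is read on the pre-mRNA sense strand ("GT" for a
    canonical donor, "AG" for a canonical acceptor).  ``critical_c_coord``
    is the genomic position of the invariant G; the base editor's substrate
    C lies on the opposite strand at that position.  ``dinuc_plus_start``
    is the plus-strand start of the 2-nt motif, used for window extraction.
    """

    kind: str  # "donor" | "acceptor"
    transcript_id: str
    intron_index: int  # 1-based
    contig: str
    strand: str
    junction_coord: int  # first (donor) / last (acceptor) intron base
    dinucleotide: str
    critical_c_coord: int
    canonical: bool
    dinuc_plus_start: int
    spliced_offset: int  # offset of the junction in the spliced transcript
    downstream_exon_index: int  # 0-based index of the exon 3' of this junction

    @property
    def site_id(self) -> str:
        return f"{self.transcript_id}:{self.kind}:{self.intron_index}"


@dataclass
class SpliceWindow:
    """Sense-strand sequence of length 2*flank + 2 centred on the junction motif."""

    site: SpliceSite
    flank: int
    sense_sequence: str
    plus_start: int  # plus-strand genomic start of the window

    def __post_init__(self) -> None:
        assert len(self.sense_sequence) == 2 * self.flank + 2


def extract_splice_sites(t: TranscriptModel, genome: GenomeSequence) -> list[SpliceSite]:
    """All donor and acceptor sites of a transcript, in transcript order.

    A transcript with n exons yields n-1 donors and n-1 acceptors; a
    single-exon transcript yields none.  The canonical flag checks GT / AG
    on the sense strand.
    """
    sites: list[SpliceSite] = []
    cum = t.exon_cumlens()
    for i in range(t.n_exons - 1):
        up = t.exons[i]
        down = t.exons[i + 1]
        if t.strand == "+":
            d_start, d_crit, d_junc = up[1], up[1], up[1]
            d_dinuc = genome.fetch(t.contig, up[1], up[1] + 2)
            a_start, a_crit, a_junc = down[0] - 2, down[0] - 1, down[0] - 1
            a_dinuc = genome.fetch(t.contig, down[0] - 2, down[0])
        else:
            d_start, d_crit, d_junc = up[0] - 2, up[0] - 1, up[0] - 1
            d_dinuc = genome.fetch_rc(t.contig, up[0] - 2, up[0])
            a_start, a_crit, a_junc = down[1], down[1], down[1]
            a_dinuc = genome.fetch_rc(t.contig, down[1], down[1] + 2)
        sites.append(
            SpliceSite(
                kind="donor",
                transcript_id=t.transcript_id,
                intron_index=i + 1,
                contig=t.contig,
                strand=t.strand,
                junction_coord=d_junc,
                dinucleotide=d_dinuc,
                critical_c_coord=d_crit,
                canonical=d_dinuc == "GT",
                dinuc_plus_start=d_start,
                spliced_offset=cum[i],
                downstream_exon_index=i + 1,
            )
        )
        sites.append(
            SpliceSite(
                kind="acceptor",
                transcript_id=t.transcript_id,
                intron_index=i + 1,
                contig=t.contig,
                strand=t.strand,
                junction_coord=a_junc,
                dinucleotide=a_dinuc,
                critical_c_coord=a_crit,
                canonical=a_dinuc == "AG",
                dinuc_plus_start=a_start,
                spliced_offset=cum[i],
                downstream_exon_index=i + 1,
            )
        )
    return sites


def splice_window(site: SpliceSite, genome: GenomeSequence, flank: int = 30) -> SpliceWindow:
    """Extract the sense-strand region around a junction motif.

    ``flank`` bases are taken on each side of the 2-nt motif; the returned
    sequence has length ``2*flank + 2`` with the motif at positions
    ``flank`` and ``flank + 1``.
    """
    if flank < MIN_FLANK:
        raise ValueError(f"flank must be >= {MIN_FLANK} nt to fit a protospacer+PAM, got {flank}")
    start = site.dinuc_plus_start - flank
    end = site.dinuc_plus_start + 2 + flank
    if start < 0 or end > genome.length(site.contig):
        raise ValueError(
            f"splice window of {site.site_id} truncated by contig {site.contig!r} end"
        )
    seq = genome.fetch(site.contig, start, end)
    if site.strand == "-":
        seq = revcomp(seq)
    return SpliceWindow(site=site, flank=flank, sense_sequence=seq, plus_start=start)


def splice_site_frame(sites: Iterable[SpliceSite]):
    """Splice-site report as a DataFrame (one row per site)."""
    import pandas as pd

    rows = [
        {
            "transcript_id": s.transcript_id,
            "kind": s.kind,
            "intron_index": s.intron_index,
            "contig": s.contig,
            "strand": s.strand,
            "junction_coord": s.junction_coord,
            "dinucleotide": s.dinucleotide,
            "critical_c_coord": s.critical_c_coord,
            "canonical": s.canonical,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "kind",
            "intron_index",
            "contig",
            "strand",
            "junction_coord",
            "dinucleotide",
            "critical_c_coord",
            "canonical",
        ],
    )
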