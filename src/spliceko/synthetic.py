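"""Deterministic synthetic loci, knockout-call matrices and ddPCR counts.

Every analysis module in this package is testable without downloads: this
module builds small artificial genes with *planted* features — canonical
(or deliberately non-canonical) splice junctions, premature-stop-editable
codons with window-compatible PAM placements, optional N-runs — and emits
standard FASTA/GTF/GFF3 plus a truth table of everything planted.  The
construction is its own oracle: the design pipeline run on the rendered
files must recover exactly the planted candidates.

Spacer sequence between planted features is sampled uniformly over
{A,C,G,T} and then *repaired*: any accidental protospacer/PAM placement
that would create an unplanned candidate is destroyed by deterministically
mutating one of its PAM bases (or, for accidental stop-editable codons,
the codon's critical base), never touching planted coordinates.  The
repair is deterministic given the seed.

Also provided: per-cell knockout-call simulation at known per-gene rates
(test harness for the composition math) and Poisson droplet-count
simulation at a known translocation frequency (test harness for the ddPCR
estimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import DdpcrAssayCounts
from .gene_model import GenomeSequence, TranscriptModel, revcomp
from .guide_design import (
    PROTOSPACER_LEN,
    BaseEditorProfile,
    find_pmstop_guides,
    find_splice_guides,
)

__all__ = [
    "PlantedSpliceGuide",
    "PlantedPmStop",
    "SyntheticLocusSpec",
    "SyntheticLocus",
    "make_synthetic_locus",
    "simulate_ko_calls",
    "simulate_ddpcr",
]

SOURCE = "spliceko_synth"


@dataclass(frozen=True)
class PlantedSpliceGuide:
    """Plant exactly one splice-disrupting candidate at a junction.

    ``window_position`` is the protospacer position (1 = PAM-distal) at
    which the critical C will sit; it must lie in the editor's window.
    """

    kind: str  # "donor" | "acceptor"
    intron_index: int  # 1-based
    window_position: int = 6


@dataclass(frozen=True)
class PlantedPmStop:
    """Plant a stop-editable codon plus a window-compatible PAM."""

    codon: str  # CAA | CAG | CGA | TGG
    codon_index: int  # 0-based codon within the CDS
    window_position: int = 6


@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Recipe for one synthetic locus; same seed -> byte-identical files."""

    seed: int = 7
    n_exons: int = 3
    exon_length: tuple[int, int] = (60, 90)
    intron_length: tuple[int, int] = (60, 90)
    strand: str = "+"
    contig: str = "synth1"
    gene_id: str = "SYNG1"
    transcript_id: str = "SYNT1"
    margin: int = 50
    coding: bool = True
    noncanonical_donors: tuple[int, ...] = ()
    noncanonical_acceptors: tuple[int, ...] = ()
    planted_guides: tuple[PlantedSpliceGuide, ...] = ()
    planted_pmstops: tuple[PlantedPmStop, ...] = ()
    n_run: tuple[int, int] | None = None  # (intron_index, length)

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("need at least one exon")
        if self.margin < 32:
            raise ValueError("margin must be >= 32 nt so extraction windows fit")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r}")
        for g in self.planted_guides:
            if g.kind not in {"donor", "acceptor"}:
                raise ValueError(f"unknown planted site kind {g.kind!r}")
            if not (1 <= g.intron_index <= self.n_exons - 1):
                raise ValueError(f"intron index {g.intron_index} out of range")
            bad = (
                self.noncanonical_donors
                if g.kind == "donor"
                else self.noncanonical_acceptors
            )
            if g.intron_index in bad:
                raise ValueError(
                    f"cannot plant a {g.kind} guide at non-canonical intron {g.intron_index}"
                )
        for p in self.planted_pmstops:
            if p.codon not in {"CAA", "CAG", "CGA", "TGG"}:
                raise ValueError(f"codon {p.codon!r} is not stop-editable")
            if not self.coding:
                raise ValueError("pmSTOP plants require a coding locus")


@dataclass
class SyntheticLocus:
    """Rendered locus: file texts, parsed models and the planted truth table."""

    spec: SyntheticLocusSpec
    fasta_text: str
    gtf_text: str
    gff3_text: str
    truth: pd.DataFrame
    genome: GenomeSequence
    transcript: TranscriptModel

    def write(self, outdir) -> dict[str, Path]:
        """Write locus.fa / locus.gtf / locus.gff3 / truth.tsv into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "locus.fa",
            "gtf": outdir / "locus.gtf",
            "gff3": outdir / "locus.gff3",
            "truth": outdir / "truth.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["gtf"].write_text(self.gtf_text)
        paths["gff3"].write_text(self.gff3_text)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


class _Builder:
    """Constructs the plus-strand rendering; strand flip happens at the end."""

    def __init__(self, spec: SyntheticLocusSpec, profile: BaseEditorProfile):
        self.spec = spec
        self.profile = profile
        self.rng = np.random.default_rng(spec.seed)
        self.protected: set[int] = set()
        self._draw_layout()
        self._draw_sequence()

    # ---- layout -----------------------------------------------------------
    def _draw_layout(self) -> None:
        s = self.spec
        lo, hi = s.exon_length
        self.exon_lens = [int(self.rng.integers(lo, hi + 1)) for _ in range(s.n_exons)]
        lo, hi = s.intron_length
        self.intron_lens = [
            int(self.rng.integers(lo, hi + 1)) for _ in range(s.n_exons - 1)
        ]
        if s.coding:
            excess = sum(self.exon_lens) % 3
            self.exon_lens[-1] -= excess  # total spliced length divisible by 3
        self.exons: list[tuple[int, int]] = []
        pos = s.margin
        for i, el in enumerate(self.exon_lens):
            self.exons.append((pos, pos + el))
            pos += el
            if i < s.n_exons - 1:
                pos += self.intron_lens[i]
        self.total_len = pos + s.margin

    def _draw_sequence(self) -> None:
        self.seq = list(self.rng.choice(list("ACGT"), size=self.total_len))

    # ---- stamping helpers -------------------------------------------------
    def stamp(self, pos: int, base: str, protect: bool = True) -> None:
        if not (0 <= pos < self.total_len):
            raise ValueError(f"infeasible spec: planted base at {pos} outside locus")
        if pos in self.protected and self.seq[pos] != base:
            raise ValueError(
                f"infeasible spec: position {pos} needed as {base!r} "
                f"but already planted as {self.seq[pos]!r}"
            )
        self.seq[pos] = base
        if protect:
            self.protected.add(pos)

    def stamp_str(self, start: int, bases: str, protect: bool = True) -> None:
        for k, b in enumerate(bases):
            self.stamp(start + k, b, protect)

    def spliced_to_local(self, q: int) -> int:
        off = 0
        for s_, e_ in self.exons:
            if q < off + (e_ - s_):
                return s_ + (q - off)
            off += e_ - s_
        raise ValueError(f"spliced position {q} beyond transcript")

    # ---- planting ---------------------------------------------------------
    def plant_all(self) -> None:
        s = self.spec
        for i in range(1, s.n_exons):
            e_up = self.exons[i - 1][1]
            s_down = self.exons[i][0]
            donor = "CA" if i in s.noncanonical_donors else "GT"
            acceptor = "TT" if i in s.noncanonical_acceptors else "AG"
            self.stamp_str(e_up, donor)
            self.stamp_str(s_down - 2, acceptor)
        if s.coding:
            self.stamp_str(self.spliced_to_local(0), "ATG")
            n_spliced = sum(self.exon_lens)
            for k, b in enumerate("TAA"):
                self.stamp(self.spliced_to_local(n_spliced - 3 + k), b)
        for p in s.planted_pmstops:
            self._plant_pmstop(p)
        for g in s.planted_guides:
            self._plant_splice_guide(g)
        if s.n_run is not None:
            self._plant_n_run(*s.n_run)

    def _codon_local_coords(self, k: int) -> list[int]:
        coords = [self.spliced_to_local(3 * k + j) for j in range(3)]
        if coords[2] - coords[0] != 2:
            raise ValueError(
                f"infeasible spec: codon {k} spans a splice junction; pick another index"
            )
        return coords

    def _plant_pmstop(self, p: PlantedPmStop) -> None:
        n_codons = sum(self.exon_lens) // 3
        if not (1 <= p.codon_index < n_codons - 1):
            raise ValueError(
                f"infeasible spec: codon index {p.codon_index} must avoid the "
                "start and stop codons"
            )
        coords = self._codon_local_coords(p.codon_index)
        self.stamp_str(coords[0], p.codon)
        wp = p.window_position
        if not (self.profile.window_start <= wp <= self.profile.window_end):
            raise ValueError(f"window position {wp} outside the editing window")
        if p.codon == "TGG":
            g1 = coords[1]
            # antisense protospacer: PAM is sense "CCN" upstream of the motif
            self._check_span(g1 + wp - 23, g1 + wp)
            self.stamp_str(g1 + wp - 23, "CC")
        else:
            c0 = coords[0]
            x = c0 - (wp - 1)
            # sense protospacer: PAM "NGG" immediately 3' of it
            self._check_span(x, x + 23)
            self.stamp_str(x + 21, "GG")

    def _plant_splice_guide(self, g: PlantedSpliceGuide) -> None:
        i = g.intron_index
        if g.kind == "donor":
            crit = self.exons[i - 1][1]  # the invariant G of GT
        else:
            crit = self.exons[i][0] - 1  # the invariant G of AG
        wp = g.window_position
        if not (self.profile.window_start <= wp <= self.profile.window_end):
            raise ValueError(f"window position {wp} outside the editing window")
        self._check_span(crit + wp - 23, crit + wp)
        self.stamp_str(crit + wp - 23, "CC")

    def _check_span(self, start: int, end: int) -> None:
        # only the functional bases of a planted candidate are protected;
        # its footprint merely has to fit inside the locus
        if start < 0 or end > self.total_len:
            raise ValueError("infeasible spec: planted footprint outside locus")

    def _plant_n_run(self, intron_index: int, length: int) -> None:
        s_i = self.exons[intron_index - 1][1]
        e_i = self.exons[intron_index][0]
        mid = (s_i + e_i) // 2
        start = mid - length // 2
        if start < s_i + 10 or start + length > e_i - 10:
            raise ValueError("infeasible spec: N-run does not fit inside the intron")
        for pos in range(start, start + length):
            self.stamp(pos, "N")

    # ---- expected candidates ----------------------------------------------
    def expected_keys(self) -> set[tuple]:
        s = self.spec
        out = set()
        for g in s.planted_guides:
            i = g.intron_index
            crit = (
                self.exons[i - 1][1] if g.kind == "donor" else self.exons[i][0] - 1
            )
            start = crit + g.window_position - PROTOSPACER_LEN
            cls = "splice_donor" if g.kind == "donor" else "splice_acceptor"
            out.add((cls, start, "-", f"{s.transcript_id}:{g.kind}:{i}"))
        for p in s.planted_pmstops:
            coords = self._codon_local_coords(p.codon_index)
            tid = f"{s.transcript_id}:codon:{p.codon_index}"
            if p.codon == "TGG":
                start = coords[1] + p.window_position - PROTOSPACER_LEN
                out.add(("pmstop", start, "-", tid))
            else:
                start = coords[0] - (p.window_position - 1)
                out.add(("pmstop", start, "+", tid))
        return out

    # ---- model assembly / repair ------------------------------------------
    def model(self) -> tuple[GenomeSequence, TranscriptModel]:
        genome = GenomeSequence({self.spec.contig: "".join(self.seq)})
        t = TranscriptModel(
            transcript_id=self.spec.transcript_id,
            gene_id=self.spec.gene_id,
            contig=self.spec.contig,
            strand="+",
            exons=list(self.exons),
            cds_intervals=list(self.exons) if self.spec.coding else [],
        )
        return genome, t

    def scan(self) -> list:
        genome, t = self.model()
        cands = []
        if t.n_exons >= 2:
            cands.extend(find_splice_guides(t, genome, self.profile))
        if self.spec.coding:
            cands.extend(find_pmstop_guides(t, genome, self.profile))
        return cands

    def repair(self, max_rounds: int = 100) -> None:
        expected = self.expected_keys()
        for _ in range(max_rounds):
            unexpected = [
                c
                for c in self.scan()
                if (c.design_class, c.start, c.genome_strand, c.target_id)
                not in expected
            ]
            if not unexpected:
                return
            unexpected.sort(key=lambda c: (c.start, c.design_class, c.target_id))
            self._kill(unexpected[0])
        raise RuntimeError(
            "repair did not converge; the spec leaves no room to remove "
            "accidental candidates"
        )

    def _kill(self, cand) -> None:
        # candidate kill sites, least invasive first: PAM bases, then (for
        # pmSTOP) the codon's editable base; replacement 'A' never seeds a
        # new PAM on either strand
        sites: list[int] = []
        if cand.genome_strand == "+":
            sites += [cand.end + 1, cand.end + 2]  # the two Gs of NGG
        else:
            sites += [cand.start - 3, cand.start - 2]  # sense "CC" of the PAM
        if cand.design_class == "pmstop":
            k = int(cand.target_id.rsplit(":", 1)[1])
            coords = [self.spliced_to_local(3 * k + j) for j in range(3)]
            sites.append(coords[1] if cand.codon_ref == "TGG" else coords[0])
        for pos in sites:
            if 0 <= pos < self.total_len and pos not in self.protected:
                self.seq[pos] = "A"
                return
        raise RuntimeError(
            f"infeasible spec: accidental candidate at {cand.start} overlaps "
            "planted features and cannot be repaired"
        )


def make_synthetic_locus(
    spec: SyntheticLocusSpec,
    outdir=None,
    profile: BaseEditorProfile | None = None,
) -> SyntheticLocus:
    """Build one synthetic locus; optionally write its files.

    The returned object carries the rendered FASTA/GTF/GFF3 texts, the
    parsed genome and transcript model, and the truth table of planted
    splice sites and guide candidates.
    """
    profile = profile or BaseEditorProfile()
    b = _Builder(spec, profile)
    b.plant_all()
    b.repair()

    seq = "".join(b.seq)
    exons = list(b.exons)
    truth_rows = _truth_rows(b, seq)
    if spec.strand == "-":
        L = b.total_len
        seq = revcomp(seq)
        exons = [(L - e, L - s) for s, e in exons][::-1]
        truth_rows = _flip_truth(truth_rows, L)
    exons_genomic = sorted(exons)

    fasta_text = _render_fasta(spec.contig, seq)
    gtf_text = _render_gtf(spec, exons_genomic)
    gff3_text = _render_gff3(spec, exons_genomic)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "feature",
            "kind",
            "index",
            "contig",
            "start",
            "end",
            "genome_strand",
            "dinucleotide",
            "canonical",
            "protospacer",
            "pam",
            "critical_positions",
        ],
    )

    # parse the rendered files back so the returned models are exactly what
    # downstream consumers will see
    import io as _io

    from .gene_model import load_genome, load_transcripts

    genome = load_genome(_io.StringIO(fasta_text))
    transcript = load_transcripts(gtf_text, genome, from_string=True)[0]

    locus = SyntheticLocus(
        spec=spec,
        fasta_text=fasta_text,
        gtf_text=gtf_text,
        gff3_text=gff3_text,
        truth=truth,
        genome=genome,
        transcript=transcript,
    )
    if outdir is not None:
        locus.write(outdir)
    return locus


def _truth_rows(b: _Builder, seq: str) -> list[dict]:
    s = b.spec
    rows: list[dict] = []
    for i in range(1, s.n_exons):
        e_up = b.exons[i - 1][1]
        s_down = b.exons[i][0]
        d_dinuc = seq[e_up : e_up + 2]
        a_dinuc = seq[s_down - 2 : s_down]
        rows.append(
            dict(
                feature="splice_site",
                kind="donor",
                index=i,
                contig=s.contig,
                start=e_up,
                end=e_up + 2,
                genome_strand="+",
                dinucleotide=d_dinuc,
                canonical=d_dinuc == "GT",
                protospacer="",
                pam="",
                critical_positions="",
            )
        )
        rows.append(
            dict(
                feature="splice_site",
                kind="acceptor",
                index=i,
                contig=s.contig,
                start=s_down - 2,
                end=s_down,
                genome_strand="+",
                dinucleotide=a_dinuc,
                canonical=a_dinuc == "AG",
                protospacer="",
                pam="",
                critical_positions="",
            )
        )
    for cls, start, strand, target in sorted(b.expected_keys()):
        end = start + PROTOSPACER_LEN
        if strand == "-":
            proto = revcomp(seq[start:end])
            pam = revcomp(seq[start - 3 : start])
        else:
            proto = seq[start:end]
            pam = seq[end : end + 3]
        kind = cls.removeprefix("splice_") if cls.startswith("splice_") else cls
        wp = _planted_window_position(b, cls, target)
        rows.append(
            dict(
                feature="guide",
                kind=cls,
                index=int(target.rsplit(":", 1)[1]),
                contig=s.contig,
                start=start,
                end=end,
                genome_strand=strand,
                dinucleotide="",
                canonical=True,
                protospacer=proto,
                pam=pam,
                critical_positions=str(wp),
            )
        )
    return rows


def _planted_window_position(b: _Builder, cls: str, target: str) -> int:
    idx = int(target.rsplit(":", 1)[1])
    if cls == "pmstop":
        for p in b.spec.planted_pmstops:
            if p.codon_index == idx:
                return p.window_position
    else:
        kind = "donor" if cls == "splice_donor" else "acceptor"
        for g in b.spec.planted_guides:
            if g.intron_index == idx and g.kind == kind:
                return g.window_position
    raise KeyError(target)


def _flip_truth(rows: list[dict], L: int) -> list[dict]:
    out = []
    for r in rows:
        r = dict(r)
        r["start"], r["end"] = L - r["end"], L - r["start"]
        r["genome_strand"] = "-" if r["genome_strand"] == "+" else "+"
        out.append(r)
    return out


def _render_fasta(contig: str, seq: str, width: int = 60) -> str:
    lines = [f">{contig}"]
    lines += [seq[i : i + width] for i in range(0, len(seq), width)]
    return "\n".join(lines) + "\n"


def _cds_frames(exons: list[tuple[int, int]], strand: str) -> list[int]:
    order = exons if strand == "+" else exons[::-1]
    frames, before = {}, 0
    for iv in order:
        frames[iv] = (3 - before % 3) % 3
        before += iv[1] - iv[0]
    return [frames[iv] for iv in exons]


def _render_gtf(spec: SyntheticLocusSpec, exons: list[tuple[int, int]]) -> str:
    g_start, g_end = exons[0][0] + 1, exons[-1][1]
    attrs = f'gene_id "{spec.gene_id}"; transcript_id "{spec.transcript_id}";'
    lines = [
        f"{spec.contig}\t{SOURCE}\tgene\t{g_start}\t{g_end}\t.\t{spec.strand}\t.\t"
        f'gene_id "{spec.gene_id}";',
        f"{spec.contig}\t{SOURCE}\ttranscript\t{g_start}\t{g_end}\t.\t{spec.strand}\t.\t{attrs}",
    ]
    for s, e in exons:
        lines.append(
            f"{spec.contig}\t{SOURCE}\texon\t{s + 1}\t{e}\t.\t{spec.strand}\t.\t{attrs}"
        )
    if spec.coding:
        for (s, e), frame in zip(exons, _cds_frames(exons, spec.strand)):
            lines.append(
                f"{spec.contig}\t{SOURCE}\tCDS\t{s + 1}\t{e}\t.\t{spec.strand}\t{frame}\t{attrs}"
            )
    return "\n".join(lines) + "\n"


def _render_gff3(spec: SyntheticLocusSpec, exons: list[tuple[int, int]]) -> str:
    g_start, g_end = exons[0][0] + 1, exons[-1][1]
    lines = [
        "##gff-version 3",
        f"{spec.contig}\t{SOURCE}\tgene\t{g_start}\t{g_end}\t.\t{spec.strand}\t.\t"
        f"ID={spec.gene_id}",
        f"{spec.contig}\t{SOURCE}\tmRNA\t{g_start}\t{g_end}\t.\t{spec.strand}\t.\t"
        f"ID={spec.transcript_id};Parent={spec.gene_id}",
    ]
    tail = f"Parent={spec.transcript_id};gene_id={spec.gene_id}"
    for s, e in exons:
        lines.append(f"{spec.contig}\t{SOURCE}\texon\t{s + 1}\t{e}\t.\t{spec.strand}\t.\t{tail}")
    if spec.coding:
        for (s, e), frame in zip(exons, _cds_frames(exons, spec.strand)):
            lines.append(
                f"{spec.contig}\t{SOURCE}\tCDS\t{s + 1}\t{e}\t.\t{spec.strand}\t{frame}\t{tail}"
            )
    return "\n".join(lines) + "\n"


# ---- stochastic simulators ------------------------------------------------


def simulate_ko_calls(
    rates,
    n_cells: int,
    seed: int,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Boolean knockout-call matrix with independent per-gene draws."""
    if isinstance(rates, dict):
        genes = list(rates)
        ps = [rates[g] for g in genes]
    else:
        ps = list(rates)
        genes = genes or [f"gene{i + 1}" for i in range(len(ps))]
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"knockout rate {p} outside [0, 1]")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    calls = rng.random((n_cells, len(ps))) < np.asarray(ps)
    return pd.DataFrame(calls, columns=genes)


def simulate_ddpcr(
    true_frequency: float,
    n_droplets: int,
    reference_lambda: float = 0.7,
    seed: int = 0,
) -> DdpcrAssayCounts:
    """Droplet counts for a duplexed assay at a known junction frequency.

    The reference channel carries ``reference_lambda`` copies/droplet; the
    junction channel carries lambda_fam = (f/100) * reference_lambda / 2
    so that the per-diploid estimator recovers ``true_frequency`` (percent)
    in expectation.  Droplet occupancy is Poisson, so a droplet is positive
    with probability 1 - exp(-lambda).
    """
    if true_frequency < 0:
        raise ValueError("frequency must be non-negative")
    if n_droplets < 1 or reference_lambda <= 0:
        raise ValueError("droplet count and reference lambda must be positive")
    rng = np.random.default_rng(seed)
    lam_fam = (true_frequency / 100.0) * reference_lambda / 2.0
    k_hex = int(rng.binomial(n_droplets, 1.0 - math.exp(-reference_lambda)))
    k_fam = int(rng.binomial(n_droplets, 1.0 - math.exp(-lam_fam)))
    return DdpcrAssayCounts(n=n_droplets, k_fam=k_fam, k_hex=k_hex)
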