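# Methods

## The knockout model

`spliceko` designs sgRNAs for cytosine base editors (CBEs): Cas9
nickase–deaminase fusions that convert C•G→T•A within an editing window
of the protospacer without inducing a double-strand break. Two knockout
mechanisms are modeled.

**Splice-site disruption.** Canonical introns begin with the donor
dinucleotide GT and end with the acceptor AG on the pre-mRNA sense
strand. The invariant G of either motif base-pairs with a cytosine on the
opposite strand; that antisense C is the editor's substrate. The design
rule is purely geometric: an antisense protospacer adjacent to a valid
PAM qualifies when the critical C lies inside the editing window. The
consequence model is categorical — *any* conversion of the critical C
(C→T target edit, C→A/C→G nontarget edits alike) destroys the motif — so
the knockout-causing fraction of critical-edited outcomes is 1 for every
splice-class guide. Donor loss is annotated as intron retention followed
by nonsense-mediated decay; acceptor loss as skipping of the downstream
exon. No splice-strength rescoring (MaxEnt or similar) is attempted: the
model asserts loss of the canonical dinucleotide, nothing finer.

Two caveats are encoded as flags rather than exclusions:
`noncoding_or_terminal_exon` on acceptor guides whose downstream exon is
the last exon or lies outside the CDS (skipping such an exon need not
abolish the protein), and `in_frame_skip` when the skipped exon length is
a multiple of 3 (the reading frame survives, so functional knockout
depends on the exon's importance).

**Premature stop (pmSTOP) introduction.** Codons one C→T edit away from a
stop: CAA→TAA, CAG→TAG, CGA→TGA on the sense strand, and TGG reached from
the antisense strand, where the Cs paired with either G yield TAG, TGA or
(both edited) TAA. Nontarget edits at the same position instead produce
missense codons — the reason pmSTOP designs are structurally less robust
than splice designs, which the outcome enumeration makes quantitative.
The terminal stop codon is excluded; codons are taken from the annotated
CDS only. Stop-codon readthrough is not modeled; the class membership
itself carries that caveat.

## Outcome enumeration

For a candidate with *m* cytosines in the editing window, all 4^m joint
assignments (T, A, G or unchanged per C) are enumerated, including the
all-unchanged outcome. Outcomes are unweighted: per-base conversion
proportions are an empirical property of a given editor and dose and are
not predicted here. Enumeration is guarded at m ≤ 8 (65 536 outcomes);
larger windows raise with advice to sample. Edits are applied on the
protospacer strand and projected onto the sense strand through the
candidate's stored local context, so classification needs no genome
access. Indel byproducts are not enumerated — they are an empirical,
low-rate side channel measured by sequencing assays, not a designed
mechanism.

## Multiplex-panel combinatorics

Simultaneous double-strand breaks at k loci admit k(k−1) directed
translocation junctions: each unordered pair contributes both reciprocal
fusion products. Inversions and large deletions are deliberately out of
scope of the count. Knockout-composition analysis takes pre-gated per-cell
boolean calls (flow gating itself is upstream) and reports the 2^g
combination categories plus fractions grouped by number of genes lost;
`expected_combination_fractions` supplies the independence benchmark
(products of per-gene rates) against which observed co-occurrence is
judged.

## Assay math

**ddPCR.** Droplet occupancy is Poisson, so channel concentration is
λ = −ln(1 − k/n) copies/droplet from k positive droplets of n. The
junction frequency is reported per diploid genome:
100 · 2 · λ_FAM / λ_HEX percent, interpreting the two-copy adjustment as
two reference sequences per genome. The factor and its placement are
config-exposed; a QuantaSoft-style alternative (doubled fractional
abundance 2·λ_FAM/(λ_FAM+λ_HEX)) is selectable, since the two agree in the
rare-event regime where such assays operate but diverge at high target
concentration. A delta-method confidence interval treats the two channels
as independent binomials. The commonly quoted 0.01% detection limit is a
reporting threshold parameter, not a hard-coded truth. Zero reference
signal and saturated channels are errors; zero FAM positives give exactly 0.

**PD-1 flow normalization.** Stimulation does not uniformly upregulate
PD-1 across control cells, so measured positive/negative percentages are
rescaled using the control-sample ratio r_PD1 of PD-1⁺ to PD-1⁻
subpopulations: F′_pos = F°_pos + F°_pos(1 − r_PD1) and
F′_neg = F°_neg − F°_pos(1 − r_PD1). The transform conserves
F_pos + F_neg exactly (an algebraic identity the tests check on random
inputs). Results outside [0, 100] are flagged and clamped only on
request.

**RNA off-target ranking.** Candidate transcripts for deaminase RNA
off-target analysis are scored by percent-maximal expression,
(Reads_CD4ᵢ · Reads_CD8ᵢ) / maxⱼ(Reads_CD4ⱼ · Reads_CD8ⱼ), filtered to
genes with previously observed editing, and the top n returned with ties
broken by gene id. The denominator is the per-gene-product maximum by
default; the product of per-compartment maxima is a selectable variant
(the two differ only when no single gene attains both maxima).

## Scoring

Published CBE window activity peaks mid-window, so
window_score = max(0, 1 − |p − mid|/w) with p the critical position (mean
when a TGG guide has two), mid the window midpoint (6 for the default
4–8 window) and w the window width (4). transcript_score = 1 − d/L
rewards lesions early in the spliced transcript, where truncation or
decay is most likely to abolish function. The combination weights
(0.7 window, 0.3 transcript) express that editability is the binding
constraint; both weights are configuration parameters, and the exact
arithmetic is this package's own concretization of those two published
principles. Ranking is fully deterministic: descending combined score,
then higher window score, smaller transcript offset, lexicographic
protospacer.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| PAM | NGG | IUPAC | SpCas9-derived BE3/BE4 |
| editing window | 4–8 | protospacer pos., 1 = PAM-distal | empirically efficient deamination band |
| extraction flank | 30 | nt/side of the junction motif | any qualifying protospacer+PAM spans ≤ [g−19, g+7] around the critical C, so ≥ 20 suffices; 30 leaves margin |
| score weights | 0.7 / 0.3 | — | editability over position; configurable |
| ddPCR reference copies | 2 | copies/genome | diploid reference locus |
| ddPCR detection limit | 0.01 | % | reporting threshold only |
| enumeration guard | 8 | window Cs | 4^8 = 65 536 outcomes |

Non-canonical (non-GT/AG) junctions are retained in extraction with
`canonical=false` but excluded from design by default (`--include-noncanonical`
to override); without the invariant G there is usually no antisense C to
edit, so the flag mainly matters for GC donors.

## The synthetic-data generator

`synthetic.make_synthetic_locus` emulates the *geometry* of real design
substrates: exon/intron structure with canonical GT/AG junctions, a
divisible-by-3 CDS opened by ATG and closed by a stop, planted
stop-editable codons, PAM anchors placed so that each planted guide's
critical C falls at a chosen window position, optional non-canonical
junctions and N-runs. Spacer sequence is uniform random; a deterministic
repair pass then rescans the locus and mutates one PAM base (or an
accidental codon's editable base) of any unplanned candidate until the
analyzers recover exactly the planted truth table. Same seed, same bytes.

What it does **not** emulate: real human TRAC/B2M/PDCD1 sequence,
realistic base composition or repeat structure, chromatin or editing
efficiency, alternative isoforms overlapping a locus. Passing tests
therefore demonstrate the correctness of the extraction/scan/classify
machinery on well-formed gene models — not the biological success rate of
designs on real genomes.

The stochastic simulators mirror the assays' generative models:
`simulate_ko_calls` draws independent per-gene Bernoulli knockouts
(n = 100 000 cells at rate 0.9³ → triple-KO ≈ 0.729 is the package's
standard self-check), and `simulate_ddpcr` draws binomial positive-droplet
counts from Poisson occupancy with λ_FAM = (f/100)·λ_HEX/2, the exact
inverse of the estimator, with a default reference load of 0.7
copies/droplet (mid dynamic range) and 20 000 droplets per well, a typical
droplet yield.

## Numerical and design choices

* Internal coordinates are 0-based half-open on the plus strand; GTF/GFF3
  1-based inclusive coordinates are converted on read. Exons and CDS
  intervals are kept in transcript (5′→3′) order.
* Guide extraction windows are clamped at contig ends inside the finders
  (placements needing absent sequence simply cannot exist), while the
  user-facing `splice_window` treats truncation as an error naming the
  site, since its contract is a fixed-width window.
* Candidates overlapping any N base are dropped entirely.
* Candidates whose critical C falls outside the window are excluded, not
  down-scored: knockout requires editing the critical base.
* Overlapping transcripts are processed independently per transcript id;
  no gene-level merging.
* Ties everywhere are broken deterministically; reruns with identical
  inputs and configuration are byte-identical, which the test suite
  checks at the file level.

## Problem sizes used in the self-checks

Fixture loci are 2–4 exons of 60–90 nt with 50-nt margins (≈ 300–700 nt
contigs); oracle-equivalence sweeps use 100 seeded loci; composition
recovery uses 100 000 simulated cells; ddPCR recovery uses 100 simulated
wells of 20 000 droplets per frequency in {0.01, 0.1, 0.5, 2.0}%. These
sizes make every property exhaustively checkable while keeping the whole
suite fast.

## Known limitations

* No off-target search or specificity scoring; orthogonal tools cover
  genome-wide placement counting and empirical off-target discovery.
* No adenine-base-editor or dual-editor chemistry.
* Consequence prediction is rule-based at the annotated junction/codon;
  no splice-strength model, no NMD-efficiency model, no readthrough rate.
* Translocation *frequencies* are not predicted from cut rates — only the
  outcome space is enumerated; frequencies come from the ddPCR assay math
  applied to measured counts.
* Outcome enumeration is unweighted; attach editor-specific conversion
  proportions downstream if probabilistic predictions are needed.
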