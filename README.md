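# spliceko

Knockout sgRNA design for **cytosine base editors** (CBEs), plus the
quantification math used to characterize multiplex editing panels.

CBEs (BE3/BE4-class Cas9 nickase–deaminase fusions) convert C•G to T•A
inside an editing window of the protospacer — no double-strand break, hence
far fewer indels and translocations than nuclease editing. `spliceko` turns
this chemistry into gene knockout designs in two ways:

* **Splice-site disruption.** A canonical intron starts with the donor
  dinucleotide `GT` and ends with the acceptor `AG` (sense strand:
  `GT:CA` / `AG:TC` with the critical antisense **C** paired to the
  invariant G). The tool extracts a window around every junction of a
  transcript, matches N20–PAM to the **antisense** strand, and keeps every
  placement whose editing window (protospacer positions 4–8, position 1 =
  PAM-distal) covers the critical C. Any conversion of that C — the
  intended C→T *or* the editor's nontarget C→A/G byproducts — removes the
  motif: donor loss predicts intron retention and nonsense-mediated decay,
  acceptor loss predicts skipping of the downstream exon.
* **Premature stop (pmSTOP) introduction.** Sense-strand codons
  `CAA→TAA`, `CAG→TAG`, `CGA→TGA`, and `TGG` edited from the antisense
  strand (`TGG→TAG/TGA/TAA`). Here nontarget edits yield missense instead
  of a stop, which is why the splice-disruption class is usually preferred.

Candidates are scored by window position (deamination is most efficient
mid-window), by transcript position (earlier lesions score higher), and a
weighted combination:

    window_score     = max(0, 1 − |p − p_mid| / w)      p = critical position
    transcript_score = 1 − d / L                        d = spliced offset, L = spliced length
    combined         = 0.7·window_score + 0.3·transcript_score

The package also implements the panel-analysis arithmetic around multiplex
experiments:

* translocation-outcome enumeration — *k* simultaneous cut sites admit
  `k(k−1)` directed junctions (4 loci → 12, 10 loci → 90);
* exhaustive enumeration of all `4^m` joint edit outcomes over the *m*
  window cytosines, with consequence classification;
* knockout-combination compositions of gated per-cell boolean phenotypes,
  and the independence benchmark `Π pᵢ / (1−pᵢ)`;
* ddPCR junction frequency from duplexed droplet counts,
  `100 · 2 · λ_FAM / λ_HEX` with `λ = −ln(1 − k/n)`;
* PD-1 flow normalization `F′_pos = F°_pos + F°_pos(1 − r_PD1)`,
  `F′_neg = F°_neg − F°_pos(1 − r_PD1)` (sum-conserving);
* RNA off-target candidate ranking by percent-maximal expression over
  CD4⁺/CD8⁺ read counts.

A deterministic synthetic-locus generator plants splice sites, editable
codons and PAM anchors with a machine-checkable truth table, so the whole
pipeline is testable without any genome download.

## Worked example

Generate a 3-exon synthetic locus with one donor guide planted at intron 1
and one acceptor guide at intron 2, then design against it:

```bash
spliceko fixtures-make -o locus --seed 7 --plant-donor 1 --plant-acceptor 2
spliceko design-splice locus/locus.fa locus/locus.gtf -t SYNT1 -o design
```

`design/guides.tsv` (columns abridged):

```
design_class     protospacer           pam  critical_positions  window_score  transcript_score  combined_score
splice_donor     TCTTACGTCTTAAGTAGTTG  TGG  6                   1             0.64257           0.892771
splice_acceptor  CTTTCCTTCATATCGGTGTT  TGG  6                   1             0.325301          0.79759
```

Both planted candidates are recovered and nothing else. Each has its
critical C at window position 6 (the window midpoint, so
`window_score = 1.0`); the donor targets intron 1, earlier in the spliced
transcript than the acceptor at intron 2, hence its higher transcript
score and rank. `design/summary.tsv` reports, over every outcome in which
the critical C is edited at all, `knockout_fraction = 1.0` for both
candidates — all three conversions of the critical C (T, A or G) destroy
the junction motif. `design/guides.bed` carries the genomic footprints
with `round(1000·combined)` as the BED score:

```
synth1  125  145  splice_donor:SYNT1     893  -
synth1  367  387  splice_acceptor:SYNT1  798  -
```

The same math is available from Python:

```python
from spliceko import PanelLocus, enumerate_translocations
panel = ["TRAC", "B2M", "PDCD1", "PDCD1_OT1"]
len(enumerate_translocations([PanelLocus(x) for x in panel]))  # -> 12
```

## Layout

```
src/spliceko/
  gene_model.py   FASTA/GTF/GFF3 input, transcript models, splice sites
  guide_design.py finders, editor profiles, scoring, ranking
  outcomes.py     4^m outcome enumeration and consequence classification
  panel.py        translocation combinatorics, KO compositions
  assays.py       ddPCR, flow normalization, RNA-OT ranking
  synthetic.py    planted-truth locus generator and simulators
  pipeline.py     end-to-end design runs
  cli.py          the `spliceko` command
docs/methods.md   model assumptions, parameter choices, limitations
```
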