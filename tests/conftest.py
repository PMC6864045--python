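import io

import pytest

from spliceko.gene_model import TranscriptModel, load_genome
from spliceko.guide_design import BaseEditorProfile
from spliceko.synthetic import (
    PlantedPmStop,
    PlantedSpliceGuide,
    SyntheticLocusSpec,
    make_synthetic_locus,
)

#: 45-nt hand-checkable locus: exon [0,30), intron "GTAAGT..." at 30, exon [36,45)
TOY_SEQ = "ATGGCTAGCAAATCCAGATCTGACTTCACAGTAAGTACACACACA"


@pytest.fixture
def profile():
    return BaseEditorProfile()


@pytest.fixture
def toy_locus():
    genome = load_genome(io.StringIO(f">chr1\n{TOY_SEQ}\n"))
    t = TranscriptModel("T1", "G1", "chr1", "+", [(0, 30), (36, 45)])
    return genome, t


@pytest.fixture(scope="session")
def planted_locus():
    """3-exon coding locus with one guide of every design class planted."""
    spec = SyntheticLocusSpec(
        seed=7,
        n_exons=3,
        exon_length=(70, 90),
        planted_guides=(
            PlantedSpliceGuide("donor", 1),
            PlantedSpliceGuide("acceptor", 2),
        ),
        planted_pmstops=(PlantedPmStop("CAA", 5), PlantedPmStop("TGG", 12)),
    )
    return make_synthetic_locus(spec)
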