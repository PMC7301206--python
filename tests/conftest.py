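import pytest

from bescan.genome_io import GeneFeature, GenomeRecord
from bescan.synthetic import FixtureBuilder


@pytest.fixture
def single_contig():
    return [GenomeRecord("c1", "AAACGGAAA")]


@pytest.fixture
def planted_builder():
    """A small fixture genome with one of each planted stop-site kind."""
    builder = FixtureBuilder(11, 3000)
    builder.plant_stop_site("CAA")
    builder.plant_stop_site("TGG")
    builder.plant_stop_site("CTG")
    builder.plant_guide_site(label="intergenic")
    return builder


@pytest.fixture
def annotated_record():
    # 30 bp contig, one forward CDS covering it all: ATG + 8 codons + TAA
    seq = "ATGCAACGACCGTTGGCAGATTGGAAATAA"
    feat = GeneFeature(locus_tag="g1", strand="+", intervals=((0, 30),))
    return GenomeRecord("c1", seq, [feat])
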