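import pytest
from hypothesis import settings

from cheops.genome_io import GeneRecord
from cheops.operon_model import Operon

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_operon(species, operon_id, layout, strand="+", start=1000,
                replicon="chr", gene_len=500, gap=200):
    """Build an operon from a layout string of che types ('ABRWY' etc.).

    The layout is transcription order; minus-strand operons are placed
    genomically reversed so transcription order matches the layout.
    """
    placed = layout if strand == "+" else layout[::-1]
    genes = []
    pos = start
    for i, t in enumerate(placed):
        genes.append(
            GeneRecord(f"{operon_id}_g{i}", species, replicon,
                       pos, pos + gene_len - 1, strand, t)
        )
        pos += gene_len + gap
    return Operon(operon_id, species, replicon, strand, tuple(genes))


@pytest.fixture
def mk_operon():
    return make_operon


@pytest.fixture
def ecoli_like():
    """Single complete operon, the textbook one-pathway species."""
    return [make_operon("ecoli", "ec_op1", "ABRWY")]


@pytest.fixture
def two_complete_plus_isolated_y():
    """Two complete operons plus a lone cheY gene, far apart."""
    return [
        make_operon("rsph", "cheOp2", "ABRWY", start=1_000),
        make_operon("rsph", "cheOp3", "ABRWY", start=900_000),
        make_operon("rsph", "isoY", "Y", start=1_800_000),
    ]
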