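import numpy as np
import pytest

from regulonmap.annotation import Gene, GenomeAnnotation, NcRNA
from regulonmap.simulate import generate_annotation, make_truth


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Three hand-placed genes (two in an operon), one ncRNA, TSS, terminator."""
    genes = {
        "geneA": Gene("geneA", "chr", "+", cds=(120, 420), utr5=(100, 120),
                      utr3=(420, 450)),
        "geneB": Gene("geneB", "chr", "+", cds=(500, 800), utr5=(480, 500),
                      utr3=(800, 830)),
        "geneC": Gene("geneC", "chr", "-", cds=(1000, 1300), utr5=(1300, 1330),
                      utr3=(970, 1000)),
    }
    ann = GenomeAnnotation(
        contigs={"chr": 2000},
        genes=genes,
        operons=[["geneA", "geneB"]],
        tss=[("chr", 100)],
        terminators=[("chr", 830, 850)],
        ncrnas={"nc1": NcRNA("nc1", "chr", "+", (1500, 1600))},
    )
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def sim_annotation():
    ann, seqs = generate_annotation(7, n_genes=30, contig_length=120_000)
    return ann, seqs


@pytest.fixture(scope="session")
def sim_truth(sim_annotation):
    ann, _ = sim_annotation
    return make_truth(ann, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
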