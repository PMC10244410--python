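import numpy as np
import pandas as pd
import pytest

from rbpedit.io_formats import PILEUP_COLUMNS, GeneModel, PileupTable


def make_pileup(rows, sample_id="test"):
    """rows: (contig, pos, strand, ref, A, C, G, T) tuples."""
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    return PileupTable(sample_id=sample_id, df=df)


@pytest.fixture
def plus_gene():
    """Coding gene on +: exon 100-900 (0-based), CDS 200-600."""
    return GeneModel(
        gene_id="gA",
        contig="chr1",
        strand="+",
        exons=((100, 900),),
        cds=((200, 600),),
        transcript_id="gA.t1",
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="gB",
        contig="chr2",
        strand="-",
        exons=((100, 900),),
        cds=((200, 600),),
        transcript_id="gB.t1",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_recovery():
    """One full-scale simulated recovery run shared across tests."""
    from rbpedit.synthetic_data import SimConfig, run_recovery

    return run_recovery(SimConfig(seed=7))
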