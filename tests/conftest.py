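import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from sacquant.codon_metrics import CodingSequence, CSCTable
from sacquant.codons import SENSE_CODONS


@pytest.fixture
def toy_csc_table():
    """Complete CSC table with small deterministic values for every sense codon."""
    rng = np.random.default_rng(12345)
    vals = pd.Series(rng.uniform(-0.5, 0.5, len(SENSE_CODONS)),
                     index=list(SENSE_CODONS))
    return CSCTable(values=vals, n_genes_used=100)


@pytest.fixture
def make_cds():
    def _make(gene_id: str, seq: str) -> CodingSequence:
        return CodingSequence.from_sequence(gene_id, seq)

    return _make
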