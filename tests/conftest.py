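import numpy as np
import pytest

from lncfunnel.io_formats import PFMRecord


def make_consensus_pfm(consensus: str, weight: float = 20.0) -> PFMRecord:
    """A sharp PFM whose consensus is the given sequence."""
    counts = np.zeros((4, len(consensus)))
    for i, base in enumerate(consensus):
        counts["ACGT".index(base), i] = weight
    return PFMRecord("Msyn", "TFsyn", counts)


@pytest.fixture
def sharp_pfm() -> PFMRecord:
    return make_consensus_pfm("ACGTACGTACG")  # 11-mer
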