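import numpy as np
import pytest

from pepmhc.peptide_data import AMINO_ACIDS, AffinityRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, length):
    aa = np.array(list(AMINO_ACIDS))
    return "".join(aa[rng.integers(0, 20, size=length)])


@pytest.fixture
def toy_records():
    return [
        AffinityRecord("HLA-A-0201", "SIINFEKL", 120.0),
        AffinityRecord("HLA-A-0201", "ACDEFGHIK", 5000.0),
        AffinityRecord("HLA-A-0201", "LMNPQRSTV", 45000.0),
    ]
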