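import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from varprio.repeats import RepeatLocus
from varprio.synthetic import DEFAULT_LOCUS_FLANKS, as_reference


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def tract_reference():
    """A small contig with embedded repeat tracts for normalization tests."""
    seq = (
        "GATTACAGGT" + "CA" * 6 + "TTGCGT" + "AGC" * 5 + "GGATC"
        + "T" * 8 + "GCAGTACGGA" + "CAG" * 7 + "TTACGGATCC"
    )
    return {"chrT": seq}


@pytest.fixture
def tract_ref_obj(tract_reference):
    return as_reference(tract_reference)


@pytest.fixture(scope="session")
def locus():
    left, right = DEFAULT_LOCUS_FLANKS
    return RepeatLocus(contig="AR", unit="CAG", left_flank=left, right_flank=right)
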