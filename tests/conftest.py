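import numpy as np
import pytest

from seqsubtype.sequence_io import STANDARD_RESIDUES, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_records(rng):
    """30 random-composition records of lengths 60-120."""
    out = []
    for i in range(30):
        length = int(rng.integers(60, 121))
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=length))
        out.append(ProteinRecord(id=f"r{i}", sequence=seq))
    return out


def make_record(seq: str, rid: str = "x") -> ProteinRecord:
    return ProteinRecord(id=rid, sequence=seq)
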