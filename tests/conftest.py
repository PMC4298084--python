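import numpy as np
import pytest

from asmeval.records import SequenceRecord
from asmeval.simulate import _random_seq


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_record(rng, name: str, n: int) -> SequenceRecord:
    return SequenceRecord(name, _random_seq(rng, n))
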