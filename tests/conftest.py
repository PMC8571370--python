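import random

import pytest

from numtriage.seqio import SequenceRecord


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def record_factory():
    def make(rec_id: str, residues: str, **kw) -> SequenceRecord:
        return SequenceRecord(rec_id, residues, **kw)

    return make


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
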