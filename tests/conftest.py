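import numpy as np
import pytest

from cisarch.seqio import MaskedSequence
from cisarch.synthetic import make_locus_fixture

#: spans of the six surveyed loci (from the assembly coordinate ranges)
LOCUS_SPANS = [8311, 10398, 10238, 18072, 17199, 14565]


def mutate(seq: MaskedSequence, rate: float, rng: np.random.Generator,
           new_id: str = "mut") -> MaskedSequence:
    """Point-mutated copy of a sequence (uniform substitutions)."""
    arr = np.array(list(seq.residues))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hit:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return MaskedSequence(id=new_id, residues="".join(arr),
                          mask=np.zeros(len(arr), dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_locus():
    return make_locus_fixture([1000], gc=0.4, rng_seed=11)[0]
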