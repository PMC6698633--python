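import numpy as np
import pytest

from rhizodem.mlst_io import LocusAlignment, MLSTDataset


@pytest.fixture
def toy_aln():
    """Four 3-bp sequences with pairwise differences {1,2,3,1,2,1}."""
    return LocusAlignment("toy", {"a": "AAA", "b": "AAT", "c": "ATT", "d": "TTT"})


@pytest.fixture
def two_locus_clonal():
    """Two perfectly correlated biallelic loci over four strains."""
    l1 = LocusAlignment("l1", {"s1": "A", "s2": "A", "s3": "C", "s4": "C"})
    l2 = LocusAlignment("l2", {"s1": "G", "s2": "G", "s3": "T", "s4": "T"})
    return MLSTDataset([l1, l2])


def random_alignment(rng, n, L, alphabet="ACGT", name="rand"):
    arr = rng.choice(list(alphabet), size=(n, L))
    return LocusAlignment(name, {f"s{i:03d}": "".join(arr[i]) for i in range(n)})


@pytest.fixture
def random_alignment_factory():
    return random_alignment
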