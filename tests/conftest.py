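import numpy as np
import pytest

from seqboost.io import FastaDataset, SequenceRecord

ALPHABET = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_example():
    """The 11-base example sequence used throughout the unit tests."""
    return SequenceRecord(id="ex1", residues="TGACCGAGAGA")


@pytest.fixture
def small_dataset():
    return FastaDataset(
        records=[
            SequenceRecord(id="g1", description="first", residues="ACGTACGT"),
            SequenceRecord(id="g2", description="second", residues="TTTTCCCC"),
            SequenceRecord(id="g3", description="third", residues="GGGGAAAA"),
        ],
        source="fixture",
    )


@pytest.fixture
def labeled_matrix(rng):
    """100 x 10 matrix: feature 0 equals the label, the rest is noise."""
    y = rng.integers(0, 2, size=100)
    X = rng.normal(size=(100, 10))
    X[:, 0] = y
    return X, y
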