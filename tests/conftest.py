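import numpy as np
import pytest

from ntaug import codon_model as cm
from ntaug.dataset import LabeledDataset, LabeledRecord


@pytest.fixture(scope="session")
def natural():
    return cm.natural_table()


@pytest.fixture(scope="session")
def all_tables(natural):
    """One table of each kind, fixed seeds."""
    return {
        "natural": natural,
        "balanced": cm.balanced_table(0),
        "shuffled": cm.shuffled_table(0),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_regression_dataset(sequences, labels=None, splits=None):
    labels = labels if labels is not None else [float(i) for i in range(len(sequences))]
    splits = splits or ["unassigned"] * len(sequences)
    records = [
        LabeledRecord(id=f"r{i}", sequence=s, label=l, split=sp)
        for i, (s, l, sp) in enumerate(zip(sequences, labels, splits))
    ]
    return LabeledDataset(records, alphabet="amino_acid", task="regression")


def make_classification_dataset(sequences, labels):
    records = [
        LabeledRecord(id=f"r{i}", sequence=s, label=float(l))
        for i, (s, l) in enumerate(zip(sequences, labels))
    ]
    return LabeledDataset(records, alphabet="amino_acid", task="classification")


@pytest.fixture(scope="session")
def aa_random_sequences():
    """A pool of random canonical amino-acid sequences of varied lengths."""
    r = np.random.default_rng(7)
    aas = list(cm.AMINO_ACIDS)
    return [
        "".join(r.choice(aas, size=int(r.integers(1, 12)))) for _ in range(40)
    ]
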