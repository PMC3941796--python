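import numpy as np
import pytest

import amypair as ap


def seqs_from_strings(strings, label="unlabeled", prefix="s"):
    return [ap.LabeledSequence.from_string(f"{prefix}{i}", s, label)
            for i, s in enumerate(strings)]


def random_sequences(rng, count, length, label="unlabeled", prefix="r"):
    out = []
    for i in range(count):
        codes = rng.integers(1, 21, size=length)
        out.append(ap.LabeledSequence(id=f"{prefix}{i}", residues=codes,
                                      label=label))
    return out


@pytest.fixture(scope="session")
def planted_dataset():
    """The reference synthetic study conditions: 100 positives / 200
    negatives of length 10, full-strength planted pentapeptide motif."""
    spec = ap.SyntheticSpec(n_pos=100, n_neg=200, seed=42)
    records, planted = ap.generate_synthetic(spec)
    return spec, records, planted


@pytest.fixture(scope="session")
def planted_model(planted_dataset):
    _, records, planted = planted_dataset
    seqs = ap.to_labeled_sequences(records)
    pos = [s for s in seqs if s.label == "positive"]
    neg = [s for s in seqs if s.label == "negative"]
    results = ap.PairCooccurrenceModel(pos, neg).fit()
    return results, seqs, planted


@pytest.fixture(scope="session")
def random_model():
    """A model fitted to unstructured random peptides (for score oracles)."""
    rng = np.random.default_rng(7)
    pos = random_sequences(rng, 20, 9, "positive", "p")
    neg = random_sequences(rng, 40, 9, "negative", "n")
    return ap.fit(pos, neg, ap.TrainingConfig(window_length=5))
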