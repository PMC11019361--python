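"""Shared fixtures: planted-motif corpora and trained models reused across
the interpretation, design and acceptance tests (training once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from secgram import curation
from secgram import models as mdl
from secgram import synthbench as sb

PLANTED = "CCTGGC"  # DNA form of the CCUGGC consensus


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture(scope="session")
def tiny_planted():
    """40 20-mers: 20 carry the planted motif (label 1), 20 do not (label 0)."""
    rng = np.random.default_rng(0)
    seqs, labels = [], []
    for _ in range(20):
        s = random_seq(rng, 20)
        off = int(rng.integers(0, 20 - len(PLANTED) + 1))
        seqs.append(s[:off] + PLANTED + s[off + len(PLANTED):])
        labels.append(1)
    for _ in range(20):
        s = random_seq(rng, 20)
        while PLANTED in s:
            s = random_seq(rng, 20)
        seqs.append(s)
        labels.append(0)
    return seqs, np.array(labels)


@pytest.fixture(scope="session")
def tiny_gru(tiny_planted):
    """GRU trained to separate the tiny planted-motif fixture."""
    seqs, labels = tiny_planted
    clf = mdl.GRUSecretionClassifier(
        hidden_size=16, n_layers=1, learning_rate=0.01, batch_size=40,
        max_epochs=200, patience=200, dropout=0.0, validation_fraction=0.0,
        random_state=0,
    )
    clf.fit(seqs, labels)
    return clf


@pytest.fixture(scope="session")
def small_bench():
    """Desk-scale planted-grammar world: 600 EC / 2,400 IC, default motifs."""
    spec = sb.BenchmarkSpec(n_ec=600, n_ic=2400, seed=7)
    records, truth = sb.make_sequence_dataset(spec)
    kept, _ = curation.curate(records)
    return spec, kept, truth


@pytest.fixture(scope="session")
def small_bench_model(small_bench):
    """GRU trained on the desk-scale benchmark, with its held-out split."""
    _, kept, _ = small_bench
    X = [r.sequence for r in kept]
    y = [r.label for r in kept]
    clf = mdl.GRUSecretionClassifier(hidden_size=32, n_layers=2, max_epochs=25,
                                     random_state=7)
    model, hist = mdl.train(clf, X, y, mdl.TrainConfig(seed=7, max_epochs=25))
    kept_recs = [kept[i] for i in hist["kept_indices"]]
    return model, kept_recs, hist


class MotifOracleModel:
    """Stand-in classifier: probability 0.95 iff the planted motif is present.

    Used as an exactly-known reference for mutagenesis and ablation logic.
    """

    max_len = 50

    def __init__(self, motif: str = PLANTED, hi: float = 0.95, lo: float = 0.05):
        self.motif = motif
        self.hi = hi
        self.lo = lo

    def secretion_probability(self, seqs):
        return np.array([self.hi if self.motif in s else self.lo for s in seqs])


@pytest.fixture
def motif_oracle():
    return MotifOracleModel()
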