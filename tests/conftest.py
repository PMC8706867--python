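import numpy as np
import pytest

from gruchem.corpus import build_vocabulary
from gruchem.synthdata import CorpusSpec, gen_corpus


@pytest.fixture(scope="session")
def toy_corpus():
    """A 600-molecule synthetic corpus with all grammar families enabled."""
    return gen_corpus(CorpusSpec(n=600, seed=42))


@pytest.fixture(scope="session")
def toy_vocab(toy_corpus):
    return build_vocabulary(toy_corpus)


@pytest.fixture(scope="session")
def tiny_lm():
    """A small GRU trained long enough to produce mostly-valid SMILES.

    Shared across LM tests; sized (2 layers x 96 units, 200-string corpus)
    so the whole fixture builds in well under a minute.
    """
    from gruchem.lm import ModelConfig, TrainConfig, train

    recs = gen_corpus(CorpusSpec(n=200, seed=7, length_range=(10, 16)))
    vocab = build_vocabulary(recs)
    seqs = [vocab.encode(r.canonical) for r in recs]
    mc = ModelConfig(vocab_size=len(vocab), embedding_dim=32, gru_layers=2,
                     hidden_units=96, max_length=60)
    tc = TrainConfig(max_steps=250, batch_size=64, seed=7)
    model = train(seqs, vocab, mc, tc)
    return model, vocab, seqs, recs
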