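"""Train a small GRU language model on a toy corpus and sample from it.

Uses a reduced architecture (2 layers x 128 units) so the script finishes in
about a minute on one CPU; the library default is the full 3 x 512 network.
"""

from gruchem.corpus import build_vocabulary
from gruchem.lm import ModelConfig, TrainConfig, sample, train
from gruchem.synthdata import CorpusSpec, gen_corpus

records = gen_corpus(CorpusSpec(n=500, seed=3, length_range=(10, 16)))
vocab = build_vocabulary(records)
seqs = [vocab.encode(r.canonical) for r in records]

mc = ModelConfig(vocab_size=len(vocab), embedding_dim=48, gru_layers=2,
                 hidden_units=128, max_length=60)
tc = TrainConfig(max_steps=1500, batch_size=64, seed=3)
model = train(seqs, vocab, mc, tc)

print(f"loss: {model.history[0]['loss']:.3f} -> {model.history[-1]['loss']:.3f}")
batch = sample(model, 500, seed=11)
print(f"sampled {batch.n_requested}, valid {batch.n_valid} "
      f"({batch.valid_fraction:.1%})")
print("examples:", *batch.strings[:5], sep="\n  ")
# The loss is the mean negative log likelihood of the next token; the valid
# fraction is the share of sampled strings the SMILES parser accepts — the
# standard sanity metric for a SMILES generator.
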