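"""Transfer learning: bias a pretrained generator toward ring-rich chemistry.

Pretrains on a general toy corpus, fine-tunes on a small aromatic-ring-biased
focused set, and measures how the sampled ring-count distribution moves.
"""

import numpy as np

from gruchem.chemspace import property_vector
from gruchem.corpus import build_vocabulary, canonicalize
from gruchem.lm import ModelConfig, TrainConfig, fine_tune, sample, train
from gruchem.synthdata import CorpusSpec, gen_corpus, gen_focused


def mean_aromatic_rings(strings):
    vals = [property_vector(canonicalize(s).canonical).aromatic_rings
            for s in strings if s and canonicalize(s).is_valid]
    return float(np.mean(vals)) if vals else float("nan")


base = gen_corpus(CorpusSpec(n=500, seed=5, length_range=(10, 16)))
focused, report = gen_focused(CorpusSpec(n=50, seed=6, length_range=(10, 16)),
                              bias="aromatic_rings", target=2.0)
print(f"focused-set mean aromatic rings: {report['focused_mean']:.2f} "
      f"(baseline {report['baseline_mean']:.2f})")

vocab = build_vocabulary(base + focused)
mc = ModelConfig(vocab_size=len(vocab), embedding_dim=48, gru_layers=2,
                 hidden_units=128, max_length=60)
model = train([vocab.encode(r.canonical) for r in base], vocab, mc,
              TrainConfig(max_steps=1200, batch_size=64, seed=5))
tuned = fine_tune(model, [vocab.encode(r.canonical) for r in focused],
                  TrainConfig(max_steps=200, batch_size=32, seed=5))

before = sample(model, 500, seed=21)
after = sample(tuned, 500, seed=21)
print(f"mean aromatic rings before: {mean_aromatic_rings(before.strings):.2f} "
      f"(validity {before.valid_fraction:.1%})")
print(f"mean aromatic rings after:  {mean_aromatic_rings(after.strings):.2f} "
      f"(validity {after.valid_fraction:.1%})")
# Fine-tuning pulls the sampled property distribution toward the focused
# set's mean — the core of the focused-library design strategy.  At this
# deliberately tiny scale validity can move a few points either way; the
# full-architecture benchmark in the test suite holds it within 5 points.
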