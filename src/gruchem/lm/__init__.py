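"""GRU-based SMILES language model: pretraining, transfer learning, sampling.

The model is an autoregressive next-token predictor over tokenized SMILES:
a 128-dimensional embedding, three GRU layers of 512 units and a softmax
output layer, trained with Adam on the mean negative log likelihood.  The
learning rate follows a stepped exponential decay: starting from 1e-3 it is
multiplied by (1 - 0.05) every 300 optimizer steps.

Transfer learning (:func:`fine_tune`) continues training of a pretrained
model on a small focused set, biasing the sampling distribution toward that
set's chemistry while (at small step counts) retaining the general SMILES
grammar learned in pretraining.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from gruchem.corpus import TokenSequence, Vocabulary, canonicalize
from gruchem.lm._gru import GRUStack

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "GenerativeModel",
    "SampleBatch",
    "learning_rate",
    "train",
    "fine_tune",
    "sample",
    "validity_fraction",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture: embedding + stacked GRU + softmax head."""

    vocab_size: int
    embedding_dim: int = 128
    gru_layers: int = 3
    hidden_units: int = 512
    max_length: int = 142  # 140-char SMILES + BOS + EOS

    def __post_init__(self):
        if self.gru_layers < 1 or self.hidden_units < 1:
            raise ValueError("gru_layers and hidden_units must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule.

    ``decay_rate`` is interpreted multiplicatively: every ``decay_every``
    steps the learning rate is multiplied by ``(1 - decay_rate)``, i.e.
    lr(step) = initial_lr * (1 - decay_rate) ** floor(step / decay_every).
    """

    max_steps: int
    initial_lr: float = 1e-3
    decay_rate: float = 0.05
    decay_every: int = 300
    batch_size: int = 128
    seed: int = 0
    eval_every: int | None = None  # log validity of 128 samples every k steps
    eval_sample_size: int = 128

    def __post_init__(self):
        if not (0.0 < self.decay_rate < 1.0):
            raise ValueError("decay_rate must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def learning_rate(tc: TrainConfig, step: int) -> float:
    """Stepped exponential decay; ``step`` counts completed optimizer steps."""
    return tc.initial_lr * (1.0 - tc.decay_rate) ** (step // tc.decay_every)


@dataclass
class SampleBatch:
    """Sampled strings with their parser-checked validity."""

    strings: list[str]
    n_requested: int

    @property
    def n_valid(self) -> int:
        return sum(1 for s in self.strings if canonicalize(s or "?").is_valid)

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n_requested


class GenerativeModel:
    """A trained (or training) SMILES generator.

    Holds the network parameters, the vocabulary it was trained with, the
    global step counter and a per-step loss history annotated with the
    training phase (``pretrain`` / ``finetune``).
    """

    def __init__(self, config: ModelConfig, vocabulary: Vocabulary, seed: int):
        if config.vocab_size != len(vocabulary):
            raise ValueError(
                f"config.vocab_size={config.vocab_size} does not match "
                f"vocabulary size {len(vocabulary)}")
        self.config = config
        self.vocabulary = vocabulary
        self.net = GRUStack(config.vocab_size, config.embedding_dim,
                            config.hidden_units, config.gru_layers,
                            np.random.default_rng(seed))
        self.step = 0
        self.history: list[dict] = []  # {step, loss, lr, phase, valid_fraction}

    # -- inference helpers -------------------------------------------------
    def next_token_distributions(self, seqs: Sequence[TokenSequence]) -> np.ndarray:
        """Per-position probability distributions over the vocabulary.

        Returns (n, T, V) probabilities for the batch (padded with PAD);
        each row sums to 1 (softmax output).
        """
        batch = _pad_batch(seqs, self.vocabulary.pad)
        return np.exp(self.net.token_log_probs(batch[:, :-1]))

    def copy(self) -> "GenerativeModel":
        dup = GenerativeModel.__new__(GenerativeModel)
        dup.config = self.config
        dup.vocabulary = self.vocabulary
        dup.net = self.net.copy()
        dup.step = self.step
        dup.history = [dict(h) for h in self.history]
        return dup

    def save_history_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["step", "loss", "lr", "phase",
                                               "valid_fraction"])
            w.writeheader()
            for row in self.history:
                w.writerow({k: row.get(k, "") for k in w.fieldnames})


def _pad_batch(seqs: Sequence[TokenSequence], pad: int) -> np.ndarray:
    T = max(s.length for s in seqs)
    out = np.full((len(seqs), T), pad, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, :s.length] = s.indices
    return out


def _check_corpus(corpus: Sequence[TokenSequence], vocab: Vocabulary) -> None:
    if len(corpus) == 0:
        raise ValueError("training corpus is empty")
    vmax = len(vocab)
    bad = [i for i, s in enumerate(corpus) if max(s.indices) >= vmax]
    if bad:
        raise ValueError(
            f"{len(bad)} sequences contain token indices outside the model "
            f"vocabulary (first offender: corpus[{bad[0]}])")


def _run_training(model: GenerativeModel, corpus: Sequence[TokenSequence],
                  tc: TrainConfig, phase: str) -> GenerativeModel:
    _check_corpus(corpus, model.vocabulary)
    rng = np.random.default_rng(tc.seed)
    pad = model.vocabulary.pad
    order: list[int] = []
    # the lr schedule runs on the local step counter, so fine-tuning
    # restarts at initial_lr (configurable through tc)
    for local_step in range(tc.max_steps):
        if len(order) < tc.batch_size:
            # new shuffled epoch; length-sort within chunks to limit padding
            idx = rng.permutation(len(corpus)).tolist()
            chunk = 8 * tc.batch_size
            idx = [j for k in range(0, len(idx), chunk)
                   for j in sorted(idx[k:k + chunk],
                                   key=lambda q: corpus[q].length)]
            order.extend(idx)
        take = [order.pop() for _ in range(min(tc.batch_size, len(order)))]
        batch = _pad_batch([corpus[i] for i in take], pad)
        inputs, targets = batch[:, :-1], batch[:, 1:]
        mask = (targets != pad).astype(np.float32)
        lr = learning_rate(tc, local_step)
        loss = model.net.train_step(inputs, targets, mask, lr)
        model.step += 1
        row = {"step": model.step, "loss": loss, "lr": lr, "phase": phase}
        if tc.eval_every and (local_step + 1) % tc.eval_every == 0:
            sb = sample(model, tc.eval_sample_size,
                        seed=tc.seed + 7919 + local_step)
            row["valid_fraction"] = sb.valid_fraction
        model.history.append(row)
    return model


def train(corpus: Sequence[TokenSequence], vocab: Vocabulary,
          mc: ModelConfig, tc: TrainConfig) -> GenerativeModel:
    """Pretrain a fresh model on an encoded corpus with its vocabulary."""
    model = GenerativeModel(mc, vocab, seed=tc.seed)
    return _run_training(model, corpus, tc, phase="pretrain")


def fine_tune(model: GenerativeModel, focused: Sequence[TokenSequence],
              tc: TrainConfig) -> GenerativeModel:
    """Transfer learning: continue training a copy on a focused set.

    The input model is left untouched; the returned copy carries the
    appended loss history with a ``finetune`` phase marker.  Sequences with
    tokens outside the model vocabulary are reported (by corpus index), not
    silently dropped.  The learning-rate schedule restarts at
    ``tc.initial_lr``.
    """
    dup = model.copy()
    if tc.max_steps == 0:
        return dup
    return _run_training(dup, focused, tc, phase="finetune")


def sample(model: GenerativeModel, n: int, seed: int,
           temperature: float = 1.0) -> SampleBatch:
    """Draw ``n`` strings by ancestral sampling (BOS → ... → EOS).

    Strings that never emit EOS are truncated at ``max_length`` and
    validity-checked as-is.  Reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v = model.vocabulary
    bodies = model.net.sample_tokens(
        n, bos=v.bos, eos=v.eos, max_length=model.config.max_length,
        rng=rng, temperature=temperature)
    strings = [v.decode(b) for b in bodies]
    return SampleBatch(strings=strings, n_requested=n)


def validity_fraction(strings: Sequence[str]) -> float:
    """Fraction of strings the SMILES parser accepts."""
    if len(strings) == 0:
        raise ValueError("empty string list")
    n_ok = sum(1 for s in strings if s and canonicalize(s).is_valid)
    return n_ok / len(strings)


# ---------------------------------------------------------------------------
# checkpoints: weights as npz + config/vocab/history as JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: GenerativeModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.params)
    meta = {
        "config": model.config.__dict__,
        "vocabulary": model.vocabulary.to_dict(),
        "step": model.step,
        "history": model.history,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_model(path: str | Path) -> GenerativeModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    mc = ModelConfig(**meta["config"])
    vocab = Vocabulary.from_dict(meta["vocabulary"])
    model = GenerativeModel(mc, vocab, seed=0)
    with np.load(path.with_suffix(".npz")) as npz:
        for k in model.net.params:
            model.net.params[k] = npz[k].astype(np.float32)
    model.step = meta["step"]
    model.history = meta["history"]
    return model
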