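"""Language-model training, schedule, sampling and transfer learning."""

import numpy as np
import pytest

from gruchem.corpus import build_vocabulary
from gruchem.lm import (
    GenerativeModel,
    ModelConfig,
    TrainConfig,
    fine_tune,
    learning_rate,
    load_model,
    sample,
    save_model,
    train,
    validity_fraction,
)


def _tiny_setup(strings, **tc_kwargs):
    v = build_vocabulary(strings)
    seqs = [v.encode(s) for s in strings]
    mc = ModelConfig(vocab_size=len(v), embedding_dim=16, gru_layers=2,
                     hidden_units=32, max_length=30)
    tc = TrainConfig(**{"max_steps": 300, "batch_size": len(strings),
                        "seed": 1, **tc_kwargs})
    return v, seqs, mc, tc


class TestSchedule:
    @pytest.mark.parametrize("step,expected", [
        (0, 0.001),
        (299, 0.001),
        (300, 0.00095),
        (600, 0.0009025),
    ])
    def test_stepped_decay(self, step, expected):
        tc = TrainConfig(max_steps=1)
        assert learning_rate(tc, step) == pytest.approx(expected, rel=1e-12)

    def test_schedule_recorded_in_history(self):
        v, seqs, mc, tc = _tiny_setup(["CCO"], max_steps=5)
        model = train(seqs, v, mc, tc)
        assert [h["lr"] for h in model.history] == [0.001] * 5

    def test_invalid_decay_rate_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(max_steps=1, decay_rate=1.5)


class TestTraining:
    def test_loss_decreases_on_single_string(self):
        v, seqs, mc, tc = _tiny_setup(["CC(=O)Nc1ccccc1"], max_steps=800)
        model = train(seqs, v, mc, tc)
        assert model.history[-1]["loss"] < model.history[0]["loss"]
        assert model.history[-1]["loss"] < 0.05  # memorized

    def test_loss_is_next_token_nll(self):
        """The recorded loss equals the mean NLL computed independently
        from the model's own next-token distributions."""
        v, seqs, mc, tc = _tiny_setup(["CCO", "CCN"], max_steps=20)
        model = train(seqs, v, mc, tc)
        probs = model.next_token_distributions(seqs)
        nll, count = 0.0, 0
        from gruchem.lm import _pad_batch
        batch = _pad_batch(seqs, v.pad)
        targets = batch[:, 1:]
        for i in range(targets.shape[0]):
            for t in range(targets.shape[1]):
                if targets[i, t] != v.pad:
                    nll -= np.log(probs[i, t, targets[i, t]])
                    count += 1
        expected = nll / count
        batch_in, batch_t = batch[:, :-1], batch[:, 1:]
        mask = (batch_t != v.pad).astype(np.float32)
        got = model.net.loss(batch_in, batch_t, mask)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_softmax_rows_normalized(self, tiny_lm):
        model, vocab, seqs, _ = tiny_lm
        probs = model.next_token_distributions(seqs[:16])
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_empty_corpus_fails_fast(self):
        v, _, mc, tc = _tiny_setup(["CCO"], max_steps=1)
        with pytest.raises(ValueError):
            train([], v, mc, tc)

    def test_vocab_mismatch_fails_fast(self):
        v, seqs, mc, tc = _tiny_setup(["CCO"], max_steps=1)
        big = build_vocabulary(["CCO", "c1ccccc1Br"])
        bad = [big.encode("c1ccccc1Br")]
        with pytest.raises(ValueError, match="outside the model vocabulary"):
            train(bad, v, mc, tc)

    def test_loss_history_reproducible(self):
        v, seqs, mc, tc = _tiny_setup(["CCO", "CCN", "CCS"], max_steps=30)
        a = train(seqs, v, mc, tc)
        b = train(seqs, v, mc, tc)
        assert [h["loss"] for h in a.history] == [h["loss"] for h in b.history]

    def test_smoothed_loss_nonincreasing(self, tiny_lm):
        """Window-averaged loss decreases over training on the toy corpus."""
        model, *_ = tiny_lm
        losses = np.array([h["loss"] for h in model.history])
        w = 50
        smoothed = np.convolve(losses, np.ones(w) / w, mode="valid")
        # each half-window-later value should not exceed the earlier one
        assert smoothed[-1] < smoothed[0]
        drops = smoothed[::w // 2]
        assert all(b <= a + 0.05 for a, b in zip(drops, drops[1:]))


class TestSampling:
    def test_memorized_string_at_low_temperature(self):
        v, seqs, mc, tc = _tiny_setup(["CCO"], max_steps=300)
        model = train(seqs, v, mc, tc)
        batch = sample(model, 20, seed=0, temperature=0.1)
        assert set(batch.strings) == {"CCO"}

    def test_same_seed_identical_batches(self, tiny_lm):
        model, *_ = tiny_lm
        a = sample(model, 64, seed=123)
        b = sample(model, 64, seed=123)
        assert a.strings == b.strings

    def test_valid_fraction_definition(self, tiny_lm):
        model, *_ = tiny_lm
        batch = sample(model, 64, seed=5)
        assert batch.n_valid <= batch.n_requested
        assert batch.valid_fraction == batch.n_valid / 64

    def test_max_length_truncation(self, tiny_lm):
        model, vocab, *_ = tiny_lm
        batch = sample(model, 32, seed=9, temperature=2.5)
        from gruchem.corpus import tokenize
        for s in batch.strings:
            # bodies can never exceed max_length tokens
            assert len(tokenize(s)) <= model.config.max_length if s else True

    def test_nonpositive_temperature_rejected(self, tiny_lm):
        model, *_ = tiny_lm
        with pytest.raises(ValueError):
            sample(model, 4, seed=0, temperature=0.0)


class TestValidityFraction:
    def test_two_thirds(self):
        assert validity_fraction(["CCO", "C(", "c1ccccc1"]) == pytest.approx(2 / 3)

    def test_all_valid(self):
        assert validity_fraction(["CCO", "CCN"]) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            validity_fraction([])


class TestFineTune:
    def test_zero_steps_is_identity(self, tiny_lm):
        model, vocab, seqs, _ = tiny_lm
        tuned = fine_tune(model, seqs[:5], TrainConfig(max_steps=0, seed=0))
        for k in model.net.params:
            assert np.array_equal(model.net.params[k], tuned.net.params[k])

    def test_original_model_untouched(self, tiny_lm):
        model, vocab, seqs, _ = tiny_lm
        before = {k: v.copy() for k, v in model.net.params.items()}
        fine_tune(model, seqs[:10],
                  TrainConfig(max_steps=10, batch_size=8, seed=0))
        for k in before:
            assert np.array_equal(before[k], model.net.params[k])

    def test_loss_drops_on_focused_set(self, tiny_lm):
        model, vocab, seqs, _ = tiny_lm
        focused = seqs[:8]
        tuned = fine_tune(model, focused,
                          TrainConfig(max_steps=60, batch_size=8, seed=0))
        ft = [h["loss"] for h in tuned.history if h["phase"] == "finetune"]
        assert ft[-1] < ft[0]

    def test_phase_marker_appended(self, tiny_lm):
        model, vocab, seqs, _ = tiny_lm
        tuned = fine_tune(model, seqs[:8],
                          TrainConfig(max_steps=5, batch_size=4, seed=0))
        phases = [h["phase"] for h in tuned.history]
        assert phases[:len(model.history)] == ["pretrain"] * len(model.history)
        assert phases[-5:] == ["finetune"] * 5

    def test_oov_focused_tokens_reported(self, tiny_lm):
        from gruchem.corpus import TokenSequence

        model, vocab, seqs, _ = tiny_lm
        # a focused sequence carrying an index the model vocabulary lacks
        bad = [TokenSequence((vocab.bos, len(vocab) + 3, vocab.eos))]
        with pytest.raises(ValueError, match="outside the model vocabulary"):
            fine_tune(model, bad, TrainConfig(max_steps=1, seed=0))


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_lm, tmp_path):
        model, *_ = tiny_lm
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert back.config == model.config
        assert back.vocabulary == model.vocabulary
        a = sample(model, 16, seed=11)
        b = sample(back, 16, seed=11)
        assert a.strings == b.strings

    def test_history_csv(self, tiny_lm, tmp_path):
        import csv

        model, *_ = tiny_lm
        p = tmp_path / "log.csv"
        model.save_history_csv(p)
        rows = list(csv.DictReader(open(p)))
        assert len(rows) == len(model.history)
        assert {"step", "loss", "lr", "phase"} <= set(rows[0])
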