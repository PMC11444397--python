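"""Schedules, training streams, the optimizer loop, and fine-tuning behavior."""

import math

import numpy as np
import pytest

import rnalm as R
from rnalm.training import (
    ConstantLR,
    LRSchedule,
    TrainConfig,
    make_training_stream,
    train,
    validation_nll,
)


class TestLRSchedule:
    @pytest.fixture
    def schedule(self):
        return LRSchedule(peak_lr=1e-3, final_lr=1e-4, warmup_epochs=0.67,
                          total_epochs=12, steps_per_epoch=300)

    def test_starts_at_zero(self, schedule):
        assert schedule.lr_at_step(0) == 0.0

    def test_peak_at_warmup_end(self, schedule):
        assert schedule.lr_at_step(schedule.warmup_steps) == pytest.approx(1e-3)

    def test_final_rate_at_last_step(self, schedule):
        assert schedule.lr_at_step(schedule.total_steps) == pytest.approx(1e-4)

    def test_piecewise_linear_and_peak_is_max(self, schedule):
        rates = [schedule.lr_at_step(s) for s in range(schedule.total_steps + 1)]
        assert max(rates) == pytest.approx(1e-3)
        # continuity: adjacent steps differ by at most the larger segment slope
        slope = 1e-3 / schedule.warmup_steps
        assert all(abs(a - b) <= slope + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_out_of_range_rejected(self, schedule):
        with pytest.raises(ValueError):
            schedule.lr_at_step(-1)
        with pytest.raises(ValueError):
            schedule.lr_at_step(schedule.total_steps + 1)

    def test_constant_schedule(self):
        sched = ConstantLR(1e-4)
        assert all(sched.lr_at_step(s) == 1e-4 for s in range(100))

    def test_validation(self):
        with pytest.raises(ValueError):
            LRSchedule(peak_lr=1e-4, final_lr=1e-3)
        with pytest.raises(ValueError):
            LRSchedule(warmup_epochs=12, total_epochs=12)


class TestTrainingStream:
    def test_two_short_sequences_one_block(self, base_tokenizer):
        stream = make_training_stream(["ACG", "TTA"], base_tokenizer, 8, seed=0)
        blocks, mask = stream.blocks(0)
        assert blocks.shape == (1, 8)
        assert mask.sum() == 8  # 3+1 + 3+1 tokens, no padding needed

    def test_token_conservation(self, base_tokenizer, small_corpus):
        stream = make_training_stream(small_corpus, base_tokenizer, 32, seed=1)
        blocks, mask = stream.blocks(0)
        total_nt = sum(len(r.sequence) for r in small_corpus)
        assert mask.sum() == total_nt + len(small_corpus)

    def test_same_seed_same_order(self, base_tokenizer, small_corpus):
        a = make_training_stream(small_corpus, base_tokenizer, 32, seed=2).blocks(0)
        b = make_training_stream(small_corpus, base_tokenizer, 32, seed=2).blocks(0)
        assert np.array_equal(a[0], b[0])

    def test_padding_is_eos_and_masked(self, base_tokenizer):
        stream = make_training_stream(["ACG"], base_tokenizer, 8, seed=0)
        blocks, mask = stream.blocks(0)
        assert list(blocks[0, 4:]) == [0, 0, 0, 0]
        assert not mask[0, 4:].any()

    def test_padded_mode_one_sequence_per_block(self, base_tokenizer):
        stream = make_training_stream(["ACG", "TTAAC"], base_tokenizer, 16,
                                      seed=0, mode="padded")
        blocks, mask = stream.blocks(0)
        assert blocks.shape[0] == 2
        for row in range(2):
            assert blocks[row, 0] == 0  # every sequence starts after EOS at position 0
        # all real tokens appear exactly once: 3+1 and 5+1 masked positions
        assert sorted(mask.sum(axis=1)) == [4, 6]

    def test_padded_mode_truncates_to_context(self, base_tokenizer):
        stream = make_training_stream(["ACGTACGT"], base_tokenizer, 6,
                                      seed=0, mode="padded")
        blocks, mask = stream.blocks(0)
        assert blocks.shape == (1, 6)
        assert mask[0, 1:].all()

    def test_unknown_mode_rejected(self, base_tokenizer):
        with pytest.raises(ValueError):
            make_training_stream(["ACG"], base_tokenizer, 8, mode="ragged")


@pytest.fixture(scope="module")
def memorizing_run(base_tokenizer):
    """Train the small config briefly on a degenerate corpus (shared by tests)."""
    seq = "ACGGTTAACCGGATCGGATC"
    cfg = R.ModelConfig(n_layers=2, d_model=64, n_heads=4, context_len=32,
                        vocab_size=5, seed=0)
    model = R.build_model(cfg)
    stream = make_training_stream([seq] * 100, base_tokenizer, 32, seed=0)
    tc = TrainConfig(schedule=ConstantLR(1e-3), batch_size=8, epochs=4, seed=0)
    return train(model, stream, [seq], tc, tokenizer=base_tokenizer)


class TestTrain:
    def test_untrained_uniform_model_ppl_near_v(self, base_tokenizer):
        cfg = R.ModelConfig(n_layers=1, d_model=16, n_heads=2, context_len=16, vocab_size=5)
        m = R.build_model(cfg)
        m.params["tok_emb"][:] = 0.0
        nll = validation_nll(m, ["ACGT"], base_tokenizer)
        assert math.exp(nll) == pytest.approx(5.0, rel=1e-6)

    def test_loss_decreases_on_degenerate_corpus(self, memorizing_run):
        _, history = memorizing_run
        assert history[-1].val_nll < history[0].val_nll
        assert history[-1].val_nll < 1.0

    def test_perplexity_is_exp_nll(self, memorizing_run):
        _, history = memorizing_run
        for h in history:
            assert h.val_ppl == pytest.approx(math.exp(h.val_nll), rel=1e-12)

    def test_early_stopping_returns_best_checkpoint(self, base_tokenizer):
        # destabilize with an oversized learning rate so validation loss is
        # non-monotone, then check the returned weights match the best epoch
        cfg = R.ModelConfig(n_layers=1, d_model=16, n_heads=2, context_len=16,
                            vocab_size=5, seed=7)
        model = R.build_model(cfg)
        stream = make_training_stream(["ACGTACGT"] * 20, base_tokenizer, 16, seed=0)
        tc = TrainConfig(schedule=ConstantLR(0.5), batch_size=4, epochs=8, seed=0,
                         early_stop_patience=2)
        model, history = train(model, stream, ["ACGTACGT"], tc, tokenizer=base_tokenizer)
        returned = validation_nll(model, ["ACGTACGT"], base_tokenizer)
        assert returned == pytest.approx(min(h.val_nll for h in history), abs=1e-9)

    def test_determinism_same_seed(self, base_tokenizer):
        def run():
            cfg = R.ModelConfig(n_layers=1, d_model=16, n_heads=2, context_len=16,
                                vocab_size=5, seed=1)
            m = R.build_model(cfg)
            stream = make_training_stream(["ACGGTA"] * 10, base_tokenizer, 16, seed=3)
            tc = TrainConfig(schedule=ConstantLR(1e-3), batch_size=4, epochs=2, seed=3)
            m, _ = train(m, stream, ["ACGGTA"], tc, tokenizer=base_tokenizer)
            return R.generate(m, base_tokenizer, "",
                              R.SamplingSpec(strategy="greedy", max_new_tokens=20)).sequence

        assert run() == run()


class TestFinetune:
    def test_constant_lr_used_every_step(self, base_tokenizer):
        cfg = R.ModelConfig(n_layers=1, d_model=16, n_heads=2, context_len=16, vocab_size=5)
        m = R.build_model(cfg)
        tc = TrainConfig(batch_size=4, epochs=2, seed=0)  # schedule defaults to 1e-4
        _, history = R.finetune(m, ["ACGTAC"] * 10, tc, base_tokenizer,
                                val_records=["ACGTAC"])
        assert all(h.lr == pytest.approx(1e-4) for h in history)

    def test_zero_epochs_leaves_model_unchanged(self, base_tokenizer, tiny_model):
        before = {k: v.copy() for k, v in tiny_model.params.items()}
        m = tiny_model.copy()
        m, history = R.finetune(m, ["ACGT"] * 4, TrainConfig(epochs=0), base_tokenizer)
        assert history == []
        assert all(np.array_equal(before[k], m.params[k]) for k in before)

    def test_finetuning_reduces_nll_of_target_distribution(self, base_tokenizer):
        # positives share an implanted word; fine-tuning must lower their NLL
        pwm = tuple(tuple(1.0 if b == c else 0.0 for b in "ACGT") for c in "TTGGCCAA")
        motif = R.MotifSpec(pwm=pwm, implant_rate=1.0, seed=2)
        pos, _ = R.generate_binding_sets(R.uniform_markov_spec(80, 30, seed=2), motif, 80, 1)
        held, trainset = pos[:10], pos[10:]
        cfg = R.ModelConfig(n_layers=2, d_model=32, n_heads=2, context_len=32,
                            vocab_size=5, seed=4)
        m = R.build_model(cfg)
        before = validation_nll(m, held, base_tokenizer)
        tc = TrainConfig(schedule=ConstantLR(1e-3), batch_size=8, epochs=6, seed=0)
        m, _ = R.finetune(m, trainset, tc, base_tokenizer)
        after = validation_nll(m, held, base_tokenizer)
        assert after < before
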