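"""Pre-training and fine-tuning loops.

Optimizer is Adam (beta1=0.9, beta2=0.999). The pre-training schedule warms
the learning rate linearly from 0 to its peak (default 1e-3) over a fractional
number of warmup epochs (default 0.67), then decays linearly to the final rate
(default 1e-4) at the last step. Fine-tuning uses a constant rate, default
1e-4, with no warmup or scheduler. Gradients are clipped at global norm 1.0
by default. Sequences are concatenated with EOS delimiters and chunked into
fixed-length blocks; the trailing partial block is EOS-filled and the filler
is excluded from the loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import LanguageModel, sequence_nll
from .tokenizer import BPETokenizer

__all__ = [
    "LRSchedule",
    "ConstantLR",
    "TrainConfig",
    "TrainingStream",
    "make_training_stream",
    "train",
    "finetune",
    "TrainingDiverged",
    "EpochStats",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class LRSchedule:
    """Linear warmup to ``peak_lr`` then linear decay to ``final_lr``."""

    peak_lr: float = 1e-3
    final_lr: float = 1e-4
    warmup_epochs: float = 0.67
    total_epochs: int = 12
    steps_per_epoch: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.final_lr <= self.peak_lr:
            raise ValueError("need 0 < final_lr <= peak_lr")
        if not 0 <= self.warmup_epochs < self.total_epochs:
            raise ValueError("need 0 <= warmup_epochs < total_epochs")
        if self.steps_per_epoch < 1:
            raise ValueError("steps_per_epoch must be >= 1")

    @property
    def warmup_steps(self) -> int:
        return int(round(self.warmup_epochs * self.steps_per_epoch))

    @property
    def total_steps(self) -> int:
        return self.total_epochs * self.steps_per_epoch

    def lr_at_step(self, step: int) -> float:
        """Piecewise-linear rate; step 0 -> 0, warmup end -> peak, last -> final."""
        if not 0 <= step <= self.total_steps:
            raise ValueError(f"step {step} outside 0..{self.total_steps}")
        w = self.warmup_steps
        if w > 0 and step <= w:
            return self.peak_lr * step / w
        if self.total_steps == w:
            return self.peak_lr
        frac = (step - w) / (self.total_steps - w)
        return self.peak_lr + (self.final_lr - self.peak_lr) * frac


@dataclass(frozen=True)
class ConstantLR:
    lr: float = 1e-4

    def lr_at_step(self, step: int) -> float:
        return self.lr


@dataclass(frozen=True)
class TrainConfig:
    schedule: object = None  # LRSchedule or ConstantLR; None -> ConstantLR(1e-4)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 32
    epochs: int = 1
    seed: int = 0
    early_stop_patience: int | None = None
    grad_clip: float | None = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.adam_beta1 < 1 and 0 < self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass(frozen=True)
class EpochStats:
    epoch: int
    train_nll: float
    val_nll: float
    val_ppl: float
    lr: float


class TrainingStream:
    """Token blocks of fixed width for one corpus; two layouts.

    ``mode="concat"`` (pre-training): sequences are concatenated with EOS
    separators in a seeded per-epoch order and chunked into ``context_len``
    blocks; every token of every sequence (plus one EOS per sequence) appears
    exactly once per epoch, and the final partial block is EOS-filled with
    the filler masked out of the loss.

    ``mode="padded"`` (fine-tuning on short independent sequences): each
    block is one sequence laid out as [EOS, tokens..., EOS, pad...], so every
    sequence starts at position 0 exactly as it does at generation time; pad
    positions are masked. Sequences longer than the context are truncated.
    """

    def __init__(self, records, tokenizer: BPETokenizer, context_len: int,
                 seed: int = 0, mode: str = "concat"):
        if mode not in ("concat", "padded"):
            raise ValueError(f"unknown stream mode {mode!r}")
        self.context_len = context_len
        self.eos_id = tokenizer.eos_id
        self.seed = seed
        self.mode = mode
        self._encoded = [
            np.asarray(tokenizer.encode(r if isinstance(r, str) else r.sequence) + [self.eos_id])
            for r in records
        ]
        self.n_real_tokens = int(sum(len(e) for e in self._encoded))
        if mode == "padded":
            self._width = min(context_len, max((len(e) for e in self._encoded), default=2) + 1)

    @property
    def n_blocks(self) -> int:
        if self.mode == "padded":
            return len(self._encoded)
        return math.ceil(self.n_real_tokens / self.context_len)

    def blocks(self, epoch: int = 0):
        """(blocks, mask) arrays of shape (n_blocks, width); seeded order."""
        rng = np.random.default_rng((self.seed, epoch))
        order = rng.permutation(len(self._encoded))
        if self.mode == "padded":
            w = self._width
            blocks = np.full((len(order), w), self.eos_id)
            mask = np.zeros((len(order), w), dtype=bool)
            for row, i in enumerate(order):
                e = self._encoded[i][: w - 1]
                blocks[row, 1 : 1 + len(e)] = e
                mask[row, 1 : 1 + len(e)] = True
            return blocks, mask
        flat = np.concatenate([self._encoded[i] for i in order]) if self._encoded else np.empty(0, int)
        n_pad = self.n_blocks * self.context_len - len(flat)
        mask = np.ones(len(flat), dtype=bool)
        flat = np.concatenate([flat, np.full(n_pad, self.eos_id)])
        mask = np.concatenate([mask, np.zeros(n_pad, dtype=bool)])
        return (
            flat.reshape(self.n_blocks, self.context_len),
            mask.reshape(self.n_blocks, self.context_len),
        )


def make_training_stream(records, tokenizer, context_len, seed: int = 0,
                         mode: str = "concat") -> TrainingStream:
    return TrainingStream(records, tokenizer, context_len, seed, mode=mode)


class _Adam:
    def __init__(self, params, cfg: TrainConfig):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.cfg = cfg

    def step(self, params, grads, lr: float) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1 - c.adam_beta1 ** self.t
        b2t = 1 - c.adam_beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + c.adam_eps)


def _clip_grads(grads, max_norm: float) -> None:
    total = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def validation_nll(model: LanguageModel, records, tokenizer: BPETokenizer) -> float:
    """Mean per-token NLL over a held-out corpus (EOS terminator included)."""
    total, n = 0.0, 0
    for r in records:
        seq = r if isinstance(r, str) else r.sequence
        ids = [tokenizer.eos_id] + tokenizer.encode(seq, add_eos=True)
        res = sequence_nll(model, ids)
        total += res.total
        n += res.n_terms
    if n == 0:
        raise ValueError("no validation tokens")
    return total / n


def train(
    model: LanguageModel,
    train_stream: TrainingStream,
    val_records,
    config: TrainConfig,
    tokenizer: BPETokenizer | None = None,
    log=None,
):
    """Minimize NLL with Adam; returns ``(model, history)``.

    With early stopping active the returned model carries the best-validation
    weights; otherwise the last. Perplexity is exp(per-token NLL) exactly.
    """
    schedule = config.schedule or ConstantLR()
    adam = _Adam(model.params, config)
    history: list[EpochStats] = []
    best_val = math.inf
    best_params = None
    bad_epochs = 0
    step = 0
    lr = 0.0
    for epoch in range(config.epochs):
        blocks, masks = train_stream.blocks(epoch)
        epoch_loss, epoch_tok = 0.0, 0
        for start in range(0, len(blocks), config.batch_size):
            xb = blocks[start : start + config.batch_size]
            mb = masks[start : start + config.batch_size]
            x, y = xb[:, :-1], xb[:, 1:]
            m = mb[:, 1:]
            if m.sum() == 0:
                continue
            loss, grads = model.loss_and_grads(x, y, m)
            if not math.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at step {step}")
            if config.grad_clip is not None:
                _clip_grads(grads, config.grad_clip)
            step += 1
            try:
                lr = schedule.lr_at_step(step)
            except ValueError:
                lr = schedule.lr_at_step(getattr(schedule, "total_steps", step))
            adam.step(model.params, grads, lr)
            epoch_loss += loss * m.sum()
            epoch_tok += int(m.sum())
        train_nll = epoch_loss / max(epoch_tok, 1)
        if val_records and tokenizer is not None:
            val_nll = validation_nll(model, val_records, tokenizer)
        else:
            val_nll = train_nll
        stats = EpochStats(epoch, float(train_nll), float(val_nll),
                           float(math.exp(val_nll)), float(lr) if step else 0.0)
        history.append(stats)
        if log:
            log(f"epoch {epoch}: train_nll={train_nll:.4f} val_nll={val_nll:.4f} "
                f"val_ppl={math.exp(val_nll):.2f} lr={stats.lr:.2e}")
        if val_nll < best_val:
            best_val = val_nll
            bad_epochs = 0
            if config.early_stop_patience is not None:
                best_params = {k: v.copy() for k, v in model.params.items()}
        else:
            bad_epochs += 1
            if config.early_stop_patience is not None and bad_epochs >= config.early_stop_patience:
                break
    if config.early_stop_patience is not None and best_params is not None:
        model.params = best_params
    return model, history


def finetune(
    model: LanguageModel,
    records,
    config: TrainConfig,
    tokenizer: BPETokenizer,
    val_records=None,
):
    """Same loop as :func:`train` with a constant learning rate (default 1e-4).

    Uses the padded one-sequence-per-block layout so fine-tuned sequences are
    conditioned exactly as they will be at generation time (EOS at position 0).
    """
    if config.schedule is None:
        config = replace(config, schedule=ConstantLR(1e-4))
    stream = make_training_stream(records, tokenizer, model.config.context_len,
                                  seed=config.seed, mode="padded")
    return train(model, stream, val_records or [], config, tokenizer=tokenizer)


def write_history_tsv(history: Sequence[EpochStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_nll\tval_nll\tval_ppl\tlr\n")
        for h in history:
            fh.write(f"{h.epoch}\t{h.train_nll:.6f}\t{h.val_nll:.6f}\t{h.val_ppl:.6f}\t{h.lr:.6e}\n")
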