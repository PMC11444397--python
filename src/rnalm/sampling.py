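"""Sequence generation: greedy search, beam search, and top-k random sampling.

Decoding starts from [EOS] + encode(prefix) and proceeds token by token until
EOS or the new-token budget. Temperature divides the logits before the
softmax; top-k renormalizes over the k largest-probability tokens. Beam search
scores hypotheses by raw summed log-probability (no length normalization);
hypotheses that emit EOS are frozen and compete at the end, and ties are
broken by the lexicographically smaller token-id sequence. Deterministic
strategies are driven by enumerating all nucleotide prefixes of a fixed
length, which yields 4^length sequences per configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import LanguageModel, forward_logprobs
from .tokenizer import BPETokenizer

__all__ = ["SamplingSpec", "GenerationResult", "generate", "enumerate_prefixes", "generate_batch"]


@dataclass(frozen=True)
class SamplingSpec:
    strategy: str = "topk"  # greedy | beam | topk
    beam_width: int = 5
    top_k: int = 40
    temperature: float = 1.0
    max_new_tokens: int | None = None  # None -> up to the model context length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("greedy", "beam", "topk"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class GenerationResult:
    sequence: str  # nucleotides, EOS stripped
    token_ids: tuple[int, ...]  # generated tokens, EOS excluded
    truncated: bool  # hit the new-token budget before EOS

    def __str__(self) -> str:
        return self.sequence


def _next_logprobs(model: LanguageModel, ids: list[int], temperature: float) -> np.ndarray:
    logits = model.forward(np.asarray(ids)[None, :])[0, -1]
    z = logits / temperature
    z = z - z.max()
    return z - np.log(np.exp(z).sum())


def _budget(model: LanguageModel, spec: SamplingSpec, prompt_len: int) -> int:
    cap = model.config.context_len - prompt_len
    if spec.max_new_tokens is None:
        return cap
    return min(spec.max_new_tokens, cap)


def generate(
    model: LanguageModel,
    tokenizer: BPETokenizer,
    prefix_nt: str = "",
    spec: SamplingSpec = SamplingSpec(),
    rng: np.random.Generator | None = None,
) -> GenerationResult:
    """Decode one sequence from a nucleotide prefix under the given strategy.

    The prefix is tokenized greedily and decoding continues at token
    granularity; the returned string includes the prefix nucleotides.
    """
    prompt = [tokenizer.eos_id] + (tokenizer.encode(prefix_nt) if prefix_nt else [])
    if len(prompt) >= model.config.context_len:
        raise ValueError("prefix does not fit in the model context")
    if spec.strategy == "beam":
        ids, truncated = _beam(model, tokenizer, prompt, spec)
    else:
        ids, truncated = _stepwise(model, tokenizer, prompt, spec, rng)
    return GenerationResult(
        sequence=prefix_nt + tokenizer.decode(ids),
        token_ids=tuple(prompt[1:]) + tuple(ids),
        truncated=truncated,
    )


def _stepwise(model, tokenizer, prompt, spec, rng):
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ids = list(prompt)
    out: list[int] = []
    budget = _budget(model, spec, len(prompt))
    for _ in range(budget):
        lp = _next_logprobs(model, ids, spec.temperature)
        if spec.strategy == "greedy" or spec.top_k == 1:
            tok = int(lp.argmax())
        else:
            k = min(spec.top_k, len(lp))
            top = np.argpartition(lp, -k)[-k:]
            p = np.exp(lp[top] - lp[top].max())
            p /= p.sum()
            tok = int(top[rng.choice(k, p=p)])
        if tok == tokenizer.eos_id:
            return out, False
        out.append(tok)
        ids.append(tok)
    return out, True


def _beam(model, tokenizer, prompt, spec):
    budget = _budget(model, spec, len(prompt))
    # hypotheses: (ids_after_prompt, logp); finished ones frozen separately
    live: list[tuple[list[int], float]] = [([], 0.0)]
    finished: list[tuple[list[int], float, bool]] = []
    for _ in range(budget):
        candidates: list[tuple[float, tuple[int, ...], int]] = []
        for toks, lp_sum in live:
            lp = _next_logprobs(model, prompt + toks, spec.temperature)
            k = min(spec.beam_width, len(lp))
            top = np.argpartition(lp, -k)[-k:]
            for t in top:
                candidates.append((lp_sum + float(lp[t]), tuple(toks), int(t)))
        # higher logp first; ties -> lexicographically smaller id sequence
        candidates.sort(key=lambda c: (-c[0], c[1] + (c[2],)))
        live = []
        for score, toks, t in candidates[: spec.beam_width]:
            if t == tokenizer.eos_id:
                finished.append((list(toks), score, False))
            else:
                live.append((list(toks) + [t], score))
        if not live:
            break
    for toks, score in live:
        finished.append((toks, score, True))
    finished.sort(key=lambda f: (-f[1], tuple(f[0])))
    ids, _, truncated = finished[0]
    return ids, truncated


def enumerate_prefixes(alphabet: Sequence[str], length: int) -> list[str]:
    """All |alphabet|^length strings in lexicographic order of the alphabet."""
    if length < 0:
        raise ValueError("length must be >= 0")
    return ["".join(p) for p in itertools.product(list(alphabet), repeat=length)]


def generate_batch(
    model: LanguageModel,
    tokenizer: BPETokenizer,
    spec: SamplingSpec,
    n: int | None = None,
    prefix_len: int = 5,
    alphabet: str = "ACGT",
) -> list[GenerationResult]:
    """A batch of generations.

    Top-k sampling draws ``n`` independent seeded sequences from the empty
    prefix. Greedy and beam search are deterministic, so the batch is driven
    by enumerating every nucleotide prefix of ``prefix_len`` (4^len sequences);
    if ``n`` is given for those strategies, the first ``n`` prefixes are used.
    """
    if spec.strategy == "topk":
        if n is None:
            raise ValueError("top-k batches need an explicit n")
        rng = np.random.default_rng(spec.seed)
        return [generate(model, tokenizer, "", spec, rng=rng) for _ in range(n)]
    prefixes = enumerate_prefixes(alphabet, prefix_len)
    if n is not None:
        prefixes = prefixes[:n]
    return [generate(model, tokenizer, p, spec) for p in prefixes]
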