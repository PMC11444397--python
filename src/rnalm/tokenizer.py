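"""Byte-pair encoding over nucleotide alphabets.

Training iteratively merges the most frequent adjacent token pair (never across
sequence boundaries) until the requested vocabulary size is reached or no pair
occurs at least twice. Pair-count ties are broken by the lexicographically
smallest concatenated string, so training is deterministic without a seed.
Token id 0 is the EOS delimiter; there is no BOS token.
"""

from __future__ import annotations

import heapq
import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

EOS_TOKEN = "<eos>"

__all__ = ["BPETokenizer", "train_bpe", "nt_per_token_stats", "EncodingError"]


class EncodingError(ValueError):
    """Raised when a sequence contains a symbol unseen during training."""


@dataclass
class BPETokenizer:
    """An ordered-merge BPE model: replaying ``merges`` regenerates ``vocab``."""

    merges: list[tuple[str, str]]
    vocab: list[str]  # id -> token string; vocab[0] is EOS
    base_symbols: list[str]
    undersized: bool = False  # corpus could not support the requested vocab size

    def __post_init__(self) -> None:
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        self.merge_rank = {pair: r for r, pair in enumerate(self.merges)}
        self._base_set = set(self.base_symbols)

    # -- core properties ----------------------------------------------------
    @property
    def eos_id(self) -> int:
        return 0

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    # -- encode / decode ----------------------------------------------------
    def encode(self, sequence: str, add_eos: bool = False) -> list[int]:
        """Greedy merge application in merge-rank order (leftmost-first on ties)."""
        for ch in sequence:
            if ch not in self._base_set:
                raise EncodingError(f"symbol {ch!r} was not seen during tokenizer training")
        tokens = self._merge_word(sequence)
        ids = [self.token_to_id[t] for t in tokens]
        if add_eos:
            ids.append(self.eos_id)
        return ids

    def _merge_word(self, sequence: str) -> list[str]:
        toks = list(sequence)
        if len(toks) < 2 or not self.merges:
            return toks
        # doubly linked list + heap of (rank, position) so equal-rank merges
        # apply leftmost-first
        nxt = list(range(1, len(toks))) + [-1]
        prv = [-1] + list(range(len(toks) - 1))
        alive = [True] * len(toks)
        heap: list[tuple[int, int]] = []
        for i in range(len(toks) - 1):
            r = self.merge_rank.get((toks[i], toks[i + 1]))
            if r is not None:
                heap.append((r, i))
        heapq.heapify(heap)
        while heap:
            r, i = heapq.heappop(heap)
            if not alive[i]:
                continue
            j = nxt[i]
            if j == -1 or not alive[j]:
                continue
            if self.merge_rank.get((toks[i], toks[j])) != r:
                continue  # stale entry
            toks[i] = toks[i] + toks[j]
            alive[j] = False
            nxt[i] = nxt[j]
            if nxt[j] != -1:
                prv[nxt[j]] = i
            p, n = prv[i], nxt[i]
            if p != -1:
                rp = self.merge_rank.get((toks[p], toks[i]))
                if rp is not None:
                    heapq.heappush(heap, (rp, p))
            if n != -1:
                rn = self.merge_rank.get((toks[i], toks[n]))
                if rn is not None:
                    heapq.heappush(heap, (rn, i))
        return [toks[i] for i in range(len(toks)) if alive[i]]

    def decode(self, ids: Iterable[int]) -> str:
        """Concatenate token strings; EOS tokens are skipped."""
        out = []
        for i in ids:
            if i == self.eos_id:
                continue
            out.append(self.vocab[i])
        return "".join(out)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "merges": [list(m) for m in self.merges],
                "vocab": self.vocab,
                "eos_id": self.eos_id,
                "base_symbols": self.base_symbols,
                "undersized": self.undersized,
            }
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "BPETokenizer":
        d = json.loads(text)
        return cls(
            merges=[tuple(m) for m in d["merges"]],
            vocab=list(d["vocab"]),
            base_symbols=list(d["base_symbols"]),
            undersized=bool(d.get("undersized", False)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "BPETokenizer":
        return cls.from_json(Path(path).read_text())


def train_bpe(corpus, vocab_size: int, seed: int = 0) -> BPETokenizer:
    """Train BPE on a corpus of SequenceRecords (or plain strings).

    ``seed`` is accepted for interface uniformity; training is fully
    deterministic (ties broken lexicographically). If no adjacent pair occurs
    at least twice before ``vocab_size`` is reached, a smaller vocabulary is
    returned with ``undersized=True`` and a warning.
    """
    seqs = [r if isinstance(r, str) else r.sequence for r in corpus]
    base_symbols = sorted({ch for s in seqs for ch in s})
    if vocab_size < len(base_symbols) + 1:
        raise ValueError(
            f"vocab_size must be at least |base symbols|+1 = {len(base_symbols) + 1}"
        )

    # token arrays with linked-list structure for incremental pair updates
    toks = [list(s) for s in seqs]
    nxts = [list(range(1, len(t))) + [-1] for t in toks]
    alive = [[True] * len(t) for t in toks]
    prvs = [[-1] + list(range(len(t) - 1)) for t in toks]

    pair_counts: Counter = Counter()
    pair_pos: dict[tuple[str, str], set[tuple[int, int]]] = defaultdict(set)
    for si, t in enumerate(toks):
        for i in range(len(t) - 1):
            pair = (t[i], t[i + 1])
            pair_counts[pair] += 1
            pair_pos[pair].add((si, i))

    def bump(pair: tuple[str, str], delta: int, pos: tuple[int, int] | None = None) -> None:
        pair_counts[pair] += delta
        if pair_counts[pair] <= 0:
            del pair_counts[pair]
        if pos is not None and delta > 0:
            pair_pos[pair].add(pos)

    merges: list[tuple[str, str]] = []
    target_merges = vocab_size - len(base_symbols) - 1
    undersized = False
    while len(merges) < target_merges:
        best = None
        best_key = None
        for pair, c in pair_counts.items():
            if c < 2:
                continue
            key = (-c, pair[0] + pair[1])
            if best_key is None or key < best_key:
                best_key = key
                best = pair
        if best is None:
            undersized = True
            break
        a, b = best
        merged = a + b
        for si, i in sorted(pair_pos.pop(best, ())):
            t, nx, pv, al = toks[si], nxts[si], prvs[si], alive[si]
            if not al[i] or t[i] != a:
                continue
            j = nx[i]
            if j == -1 or not al[j] or t[j] != b:
                continue
            p, n = pv[i], nx[j]
            # destroyed pairs
            bump((a, b), -1)
            if p != -1:
                bump((t[p], a), -1)
            if n != -1:
                bump((b, t[n]), -1)
            # apply the merge
            t[i] = merged
            al[j] = False
            nx[i] = n
            if n != -1:
                pv[n] = i
            # created pairs
            if p != -1:
                bump((t[p], merged), +1, (si, p))
            if n != -1:
                bump((merged, t[n]), +1, (si, i))
        merges.append((a, b))

    if undersized:
        warnings.warn(
            f"corpus supports only {len(merges)} merges; vocabulary has "
            f"{1 + len(base_symbols) + len(merges)} tokens instead of {vocab_size}",
            stacklevel=2,
        )
    vocab = [EOS_TOKEN] + base_symbols + [a + b for a, b in merges]
    return BPETokenizer(merges=merges, vocab=vocab, base_symbols=base_symbols, undersized=undersized)


def nt_per_token_stats(model: BPETokenizer, corpus) -> float:
    """Mean nucleotides per token over a corpus, EOS excluded."""
    seqs = [r if isinstance(r, str) else r.sequence for r in corpus]
    if not seqs:
        raise ValueError("empty corpus")
    total_nt = sum(len(s) for s in seqs)
    total_tokens = sum(len(model.encode(s)) for s in seqs)
    return total_nt / total_tokens
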