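"""Synthetic nucleotide corpora for testing and demonstration.

Three generators: Markov background corpora with controllable k-mer structure,
designed hairpin corpora (a perfect stem-loop exists by construction), and
motif-implanted positive/negative sets that emulate CLIP-style protein-binding
data. All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import SequenceRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "MarkovSpec",
    "MotifSpec",
    "uniform_markov_spec",
    "generate_markov_corpus",
    "generate_hairpin_corpus",
    "generate_binding_sets",
    "reverse_complement",
    "consensus",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MarkovSpec:
    """Order-m Markov chain over {A,C,G,T} with a named length distribution.

    ``transition_probabilities`` maps every length-``order`` context (the empty
    string for order 0) to a 4-vector of probabilities in ACGT order.
    ``length_distribution`` is ("constant", n) or ("uniform", lo, hi) in nt.
    """

    order: int
    transition_probabilities: Mapping[str, Sequence[float]]
    length_distribution: tuple
    n_sequences: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.order <= 3:
            raise ValueError("order must be in 0..3")
        contexts = ["".join(c) for c in itertools.product(BASES, repeat=self.order)]
        for ctx in contexts:
            if ctx not in self.transition_probabilities:
                raise ValueError(f"missing transition context {ctx!r}")
            p = np.asarray(self.transition_probabilities[ctx], dtype=float)
            if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"context {ctx!r}: probabilities must be a 4-vector summing to 1")
        name = self.length_distribution[0]
        if name == "constant":
            (_, n) = self.length_distribution
            if n < 1:
                raise ValueError("minimum length is 1")
        elif name == "uniform":
            (_, lo, hi) = self.length_distribution
            if lo < 1 or hi < lo:
                raise ValueError("uniform lengths need 1 <= lo <= hi")
        else:
            raise ValueError(f"unknown length distribution {name!r}")
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")

    def min_length(self) -> int:
        if self.length_distribution[0] == "constant":
            return self.length_distribution[1]
        return self.length_distribution[1]


def uniform_markov_spec(n_sequences: int, length, seed: int = 0) -> MarkovSpec:
    """Order-0 uniform background; ``length`` is an int or a (lo, hi) pair."""
    dist = ("constant", length) if isinstance(length, int) else ("uniform", *length)
    return MarkovSpec(
        order=0,
        transition_probabilities={"": (0.25, 0.25, 0.25, 0.25)},
        length_distribution=dist,
        n_sequences=n_sequences,
        seed=seed,
    )


@dataclass(frozen=True)
class MotifSpec:
    """A PWM motif (rows = positions, columns = ACGT probabilities)."""

    pwm: tuple  # w x 4, rows sum to 1
    implant_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError("pwm must be w x 4")
        if not 4 <= pwm.shape[0] <= 20:
            raise ValueError("motif width must be in 4..20")
        if (pwm < 0).any() or np.abs(pwm.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each PWM row must sum to 1")
        if not 0.0 <= self.implant_rate <= 1.0:
            raise ValueError("implant_rate must be in [0, 1]")
        object.__setattr__(self, "pwm", tuple(map(tuple, pwm)))

    @property
    def width(self) -> int:
        return len(self.pwm)

    def matrix(self) -> np.ndarray:
        return np.asarray(self.pwm, dtype=float)


def consensus(motif: MotifSpec) -> str:
    return "".join(BASES[i] for i in motif.matrix().argmax(axis=1))


def _draw_length(rng: np.random.Generator, dist: tuple) -> int:
    if dist[0] == "constant":
        return dist[1]
    _, lo, hi = dist
    return int(rng.integers(lo, hi + 1))


def _sample_markov(rng: np.random.Generator, spec: MarkovSpec, length: int) -> str:
    trans = {c: np.asarray(p, float) for c, p in spec.transition_probabilities.items()}
    chars: list[str] = []
    if spec.order == 0:
        p = trans[""]
        idx = rng.choice(4, size=length, p=p)
        return "".join(BASES[i] for i in idx)
    # higher order: seed the first `order` bases uniformly, then walk the chain
    for _ in range(min(spec.order, length)):
        chars.append(BASES[rng.integers(4)])
    while len(chars) < length:
        ctx = "".join(chars[-spec.order :])
        chars.append(BASES[rng.choice(4, p=trans[ctx])])
    return "".join(chars)


def generate_markov_corpus(spec: MarkovSpec) -> list[SequenceRecord]:
    """Sample ``spec.n_sequences`` background sequences; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_sequences):
        length = _draw_length(rng, spec.length_distribution)
        records.append(SequenceRecord(id=f"markov_{i}", sequence=_sample_markov(rng, spec, length)))
    return records


def generate_hairpin_corpus(n: int, stem_len: int, loop_len: int, seed: int = 0) -> list[SequenceRecord]:
    """Sequences of the form stem + loop + reverse_complement(stem).

    Every record admits a perfect hairpin of ``stem_len`` base pairs; the loop
    must be at least 3 nt so the hairpin is sterically possible.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if stem_len < 1:
        raise ValueError("stem_len must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        stem = "".join(BASES[j] for j in rng.integers(4, size=stem_len))
        loop = "".join(BASES[j] for j in rng.integers(4, size=loop_len))
        records.append(
            SequenceRecord(id=f"hairpin_{i}", sequence=stem + loop + reverse_complement(stem))
        )
    return records


def _implant(rng: np.random.Generator, seq: str, pwm: np.ndarray) -> str:
    w = pwm.shape[0]
    pos = int(rng.integers(0, len(seq) - w + 1))
    inst = "".join(BASES[rng.choice(4, p=pwm[j])] for j in range(w))
    # overwrite, not insert: keeps lengths identical to the background draw
    return seq[:pos] + inst + seq[pos + w :]


def generate_binding_sets(
    background: MarkovSpec,
    motif: MotifSpec,
    n_pos: int,
    n_neg: int,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Motif-implanted positives plus pure-background negatives, labeled.

    Positives carry one PWM-sampled motif instance at a uniformly random
    position with probability ``motif.implant_rate``; implantation overwrites
    ``w`` positions so positives and negatives are length-matched.
    """
    if motif.width > background.min_length():
        raise ValueError("motif wider than the minimum background sequence length")
    rng = np.random.default_rng(motif.seed)
    pwm = motif.matrix()
    positives, negatives = [], []
    for i in range(n_pos):
        length = _draw_length(rng, background.length_distribution)
        seq = _sample_markov(rng, background, length)
        if rng.random() < motif.implant_rate:
            seq = _implant(rng, seq, pwm)
        positives.append(SequenceRecord(id=f"pos_{i}", sequence=seq, label="positive"))
    for i in range(n_neg):
        length = _draw_length(rng, background.length_distribution)
        negatives.append(
            SequenceRecord(
                id=f"neg_{i}", sequence=_sample_markov(rng, background, length), label="negative"
            )
        )
    return positives, negatives
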