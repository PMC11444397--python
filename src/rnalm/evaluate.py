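"""Evaluation statistics for generated sequence sets.

Covers sliding-window k-mer distributions and their Kullback-Leibler
divergence (natural log, so nats), the control-sequence generators used in
the folding experiments (length-matched random sequences, length-matched
natural samples, exact k-let-preserving shuffles, token-level shuffles), the
four-group folding-score comparison with Mann-Whitney rank tests, and
length-binned lower-score proportions.

The k-let shuffle is the exact construction: a uniformly random Eulerian walk
on the (k-1)-mer de Bruijn multigraph, obtained by sampling a uniform in-tree
toward the terminal vertex with Wilson's loop-erased random walk and ordering
each vertex's remaining out-edges uniformly at random with the tree edge
last. The output preserves the exact multiset of k-mers, the first and last
(k-1)-mer, and the length.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .folding import FoldResult, NussinovBackend

BASES = "ACGT"
_BASE_TO_I = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "KmerDistribution",
    "kmer_counts",
    "kl_divergence",
    "klet_shuffle",
    "random_matched",
    "length_matched_sample",
    "token_shuffle_decode",
    "GroupMFEResult",
    "mfe_group_experiment",
    "binned_lower_mfe_fraction",
]


@dataclass(frozen=True)
class KmerDistribution:
    """Counts over the 4^k k-mers in lexicographic (A<C<G<T) order."""

    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4^{self.k}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def kmer_labels(self) -> list[str]:
        return ["".join(p) for p in itertools.product(BASES, repeat=self.k)]


def kmer_counts(sequences, k: int) -> KmerDistribution:
    """Sliding-window (stride 1) k-mer counts; windows with ambiguity codes skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = [s if isinstance(s, str) else s.sequence for s in sequences]
    counts = np.zeros(4**k, dtype=np.int64)
    usable = False
    for s in seqs:
        if len(s) >= k:
            usable = True
        code = np.array([_BASE_TO_I.get(c, -1) for c in s], dtype=np.int64)
        if len(code) < k:
            continue
        # rolling base-4 encoding; any window touching a -1 is skipped
        idx = np.zeros(len(code) - k + 1, dtype=np.int64)
        valid = np.ones(len(code) - k + 1, dtype=bool)
        for j in range(k):
            window = code[j : j + len(idx)]
            idx = idx * 4 + np.where(window >= 0, window, 0)
            valid &= window >= 0
        np.add.at(counts, idx[valid], 1)
    if not usable:
        warnings.warn(f"no sequence of length >= k={k}; zero-count distribution", stacklevel=2)
    return KmerDistribution(k=k, counts=counts)


def kl_divergence(P: KmerDistribution, Q: KmerDistribution, pseudocount: float = 1.0) -> float:
    """KL(P || Q) in nats after adding ``pseudocount`` to both count vectors.

    Terms with P(i)=0 contribute 0. With pseudocount 0 and any k-mer having
    Q(i)=0 < P(i), the divergence is infinite and returned as inf (warned).
    """
    if P.k != Q.k:
        raise ValueError("distributions must share k")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = P.counts + pseudocount
    q = Q.counts + pseudocount
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("cannot compare empty distributions")
    p = p / p.sum()
    q = q / q.sum()
    support = p > 0
    if (q[support] == 0).any():
        warnings.warn("Q has zero mass where P > 0; KL divergence is infinite", stacklevel=2)
        return float("inf")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


# ---------------------------------------------------------------------------
# k-let-preserving shuffle (random Eulerian walk, Wilson in-tree sampling)

def klet_shuffle(sequence: str, k: int, seed: int = 0) -> str:
    """Uniform shuffle preserving the exact multiset of k-mers.

    Sequences of length <= k admit only themselves and are returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequence)
    if n <= k:
        return sequence
    rng = np.random.default_rng(seed)
    if k == 1:
        chars = list(sequence)
        rng.shuffle(chars)
        return "".join(chars)

    km1 = k - 1
    adj: dict[str, list[str]] = {}
    for i in range(n - km1):
        u, v = sequence[i : i + km1], sequence[i + 1 : i + 1 + km1]
        adj.setdefault(u, []).append(v)
    start = sequence[:km1]
    root = sequence[n - km1 :]

    # Wilson's loop-erased random walks: uniform in-tree toward the terminal vertex
    tree: dict[str, str | None] = {root: None}
    for v in adj:
        if v in tree:
            continue
        path = [v]
        pos = {v: 0}
        u = v
        while u not in tree:
            w = adj[u][rng.integers(len(adj[u]))]
            if w in pos:
                for x in path[pos[w] + 1 :]:
                    del pos[x]
                del path[pos[w] + 1 :]
            elif w in tree:
                path.append(w)
                break
            else:
                path.append(w)
                pos[w] = len(path) - 1
            u = w
        for a, b in zip(path, path[1:]):
            tree[a] = b

    # order out-edges uniformly; each non-root vertex keeps one tree edge last
    ordered: dict[str, list[str]] = {}
    for v, targets in adj.items():
        t = list(targets)
        rng.shuffle(t)
        if v != root and tree.get(v) is not None:
            t.remove(tree[v])  # one copy of the tree edge, placed last
            t.append(tree[v])
        ordered[v] = t

    out = list(sequence[:km1])
    ptr = {v: 0 for v in ordered}
    cur = start
    total_edges = n - km1
    for _ in range(total_edges):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt[-1])
        cur = nxt
    return "".join(out)


def random_matched(sequences, seed: int = 0) -> list[str]:
    """One uniform-random ACGT sequence per input, matching each length."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sequences:
        s = s if isinstance(s, str) else s.sequence
        out.append("".join(BASES[i] for i in rng.integers(4, size=len(s))))
    return out


def length_matched_sample(pool, target_lengths, bin_width: int = 50, seed: int = 0):
    """Sample from ``pool`` matching the binned length histogram of the targets.

    Raises ValueError naming every deficient bin when the pool cannot cover a
    bin's demand. Sampling is without replacement within each bin.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    rng = np.random.default_rng(seed)
    by_bin: dict[int, list] = {}
    for rec in pool:
        s = rec if isinstance(rec, str) else rec.sequence
        by_bin.setdefault(len(s) // bin_width, []).append(rec)
    demand: dict[int, int] = {}
    for L in target_lengths:
        demand[L // bin_width] = demand.get(L // bin_width, 0) + 1
    deficient = {
        b: (need, len(by_bin.get(b, [])))
        for b, need in demand.items()
        if len(by_bin.get(b, [])) < need
    }
    if deficient:
        msg = ", ".join(
            f"[{b * bin_width},{(b + 1) * bin_width}) needs {need} has {have}"
            for b, (need, have) in sorted(deficient.items())
        )
        raise ValueError(f"pool deficient in length bins: {msg}")
    sample = []
    for b, need in sorted(demand.items()):
        chosen = rng.choice(len(by_bin[b]), size=need, replace=False)
        sample.extend(by_bin[b][i] for i in chosen)
    return sample


def token_shuffle_decode(ids, tokenizer, seed: int = 0) -> str:
    """Uniformly permute a token-id list, then decode to nucleotides.

    Nucleotides within one token stay adjacent; the token multiset and the
    decoded length are preserved while the global context is destroyed.
    """
    ids = [int(i) for i in ids]
    if any(i == tokenizer.eos_id for i in ids):
        raise ValueError("token list must be EOS-free")
    rng = np.random.default_rng(seed)
    perm = list(ids)
    rng.shuffle(perm)
    return tokenizer.decode(perm)


# ---------------------------------------------------------------------------
# group folding experiment

@dataclass(frozen=True)
class GroupMFEResult:
    scores: dict  # group name -> list of scores
    means: dict  # group name -> mean score
    tests: dict  # comparison name -> {statistic, p_value, alternative}
    backend_id: str


def _fold_all(seqs, backend) -> list[float]:
    return [backend.fold(s).score for s in seqs]


def mfe_group_experiment(
    generated,
    natural_pool,
    k_shuffle: int = 3,
    backend=None,
    seed: int = 0,
    bin_width: int = 50,
) -> GroupMFEResult:
    """Score four length-matched groups and compare them by rank tests.

    Groups: generated; natural (sampled from the pool with the generated
    length histogram); random (uniform ACGT, per-sequence length match);
    shuffled (k-let shuffle of each generated sequence). Tests: generated vs
    natural two-sided; generated vs shuffled and vs random one-sided (lower
    scores for generated).
    """
    backend = backend or NussinovBackend()
    gen = [s if isinstance(s, str) else s.sequence for s in generated]
    if not gen:
        raise ValueError("no generated sequences")
    rng = np.random.default_rng(seed)
    natural = [
        r if isinstance(r, str) else r.sequence
        for r in length_matched_sample(
            natural_pool, [len(s) for s in gen], bin_width=bin_width,
            seed=int(rng.integers(2**31)),
        )
    ]
    random_grp = random_matched(gen, seed=int(rng.integers(2**31)))
    shuffled = [klet_shuffle(s, k_shuffle, seed=int(rng.integers(2**31))) for s in gen]

    scores = {
        "generated": _fold_all(gen, backend),
        "natural": _fold_all(natural, backend),
        "random": _fold_all(random_grp, backend),
        "shuffled": _fold_all(shuffled, backend),
    }
    means = {g: float(np.mean(v)) for g, v in scores.items()}

    def test(a, b, alternative):
        stat, p = mannwhitneyu(scores[a], scores[b], alternative=alternative)
        return {"statistic": float(stat), "p_value": float(p), "alternative": alternative}

    tests = {
        "generated_vs_natural": test("generated", "natural", "two-sided"),
        "generated_vs_shuffled": test("generated", "shuffled", "less"),
        "generated_vs_random": test("generated", "random", "less"),
    }
    return GroupMFEResult(scores=scores, means=means, tests=tests, backend_id=backend.backend_id)


def binned_lower_mfe_fraction(
    generated,
    k_shuffle: int = 3,
    bin_width: int = 50,
    backend=None,
    seed: int = 0,
) -> dict[int, float]:
    """Per length bin: fraction of sequences scoring strictly below their own shuffle.

    Keys are bin lower bounds in nt; empty bins are absent (missing, not 0).
    Ties count as not-lower.
    """
    backend = backend or NussinovBackend()
    rng = np.random.default_rng(seed)
    lower: dict[int, list[bool]] = {}
    for s in generated:
        s = s if isinstance(s, str) else s.sequence
        shuf = klet_shuffle(s, k_shuffle, seed=int(rng.integers(2**31)))
        b = (len(s) // bin_width) * bin_width
        lower.setdefault(b, []).append(backend.fold(s).score < backend.fold(shuf).score)
    return {b: float(np.mean(v)) for b, v in sorted(lower.items())}
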