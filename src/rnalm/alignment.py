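"""Local alignment, identity, and novelty search.

Identity of an alignment is 100 * n_identical / n_align, where n_align counts
every column of the best local alignment (gap columns included) and
n_identical counts columns with the same unambiguous nucleotide on both rows;
ambiguity codes never count as identities. Novelty search is a seeded
Smith-Waterman: only database entries sharing at least one ``min_word``-mer
with the query are aligned (match +1, mismatch -1, gap open -2, extend -1),
and significance is calibrated empirically on a k-let-shuffled decoy database:
the e-value of a hit with score s is the number of decoy targets reaching s
for that query. Queries are classified identical-hit / partial-hit / no-hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentHit",
    "NoveltyResult",
    "alignment_identity",
    "local_align",
    "novelty_search",
]

_IUPAC = "ACGTRYSWKMBDHVN"


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    n_identical: int
    n_align: int
    identity: float  # percent
    score: float
    e_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_identical <= self.n_align:
            raise ValueError("need 0 <= n_identical <= n_align")


@dataclass(frozen=True)
class NoveltyResult:
    query_id: str
    hit: AlignmentHit | None
    category: str  # identical | partial | no_hit


def alignment_identity(n_identical: int, n_align: int) -> float:
    """Percent identity: 100 * n_identical / n_align."""
    if n_align <= 0:
        raise ValueError("n_align must be positive")
    if not 0 <= n_identical <= n_align:
        raise ValueError("need 0 <= n_identical <= n_align")
    return 100.0 * n_identical / n_align


@lru_cache(maxsize=1)
def _make_aligner() -> Align.PairwiseAligner:
    m = substitution_matrices.Array(alphabet=_IUPAC, dims=2)
    m[:, :] = -1.0
    for b in "ACGT":
        m[b, b] = 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_align(query: str, target: str, query_id: str = "", target_id: str = "") -> AlignmentHit | None:
    """Best Smith-Waterman local alignment, or None when no scoring alignment exists."""
    aligner = _make_aligner()
    alignments = aligner.align(query.upper(), target.upper())
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    row_q, row_t = str(best[0]), str(best[1])
    n_align = len(row_q)
    n_identical = sum(1 for a, b in zip(row_q, row_t) if a == b and a in "ACGT")
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        n_identical=n_identical,
        n_align=n_align,
        identity=alignment_identity(n_identical, n_align),
        score=float(best.score),
    )


def _word_index(seqs: list[str], w: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, s in enumerate(seqs):
        for j in range(len(s) - w + 1):
            index.setdefault(s[j : j + w], set()).add(i)
    return index


def _candidates(query: str, index: dict[str, set[int]], w: int) -> set[int]:
    out: set[int] = set()
    for j in range(len(query) - w + 1):
        out |= index.get(query[j : j + w], set())
    return out


def _best_hit(query, qid, cand, seqs, ids) -> AlignmentHit | None:
    best: AlignmentHit | None = None
    for i in sorted(cand):
        hit = local_align(query, seqs[i], qid, ids[i])
        if hit is None:
            continue
        if best is None or hit.score > best.score or (
            hit.score == best.score and hit.identity > best.identity
        ):
            best = hit
    return best


def novelty_search(
    queries,
    database,
    min_word: int = 7,
    evalue_threshold: float = 0.1,
    seed: int = 0,
    decoy_k: int = 2,
) -> list[NoveltyResult]:
    """Per-query best database hit with decoy-calibrated significance.

    A hit is significant when its empirical e-value (count of k-let-shuffled
    decoy targets reaching its score) is at most ``evalue_threshold``;
    significant hits at exactly 100% identity are classed ``identical``, other
    significant hits ``partial``, everything else ``no_hit``.
    """
    from .evaluate import klet_shuffle

    if not database:
        raise ValueError("database must be non-empty")
    q_seqs = [r if isinstance(r, str) else r.sequence for r in queries]
    q_ids = [f"q{i}" if isinstance(r, str) else r.id for i, r in enumerate(queries)]
    db_seqs = [r if isinstance(r, str) else r.sequence for r in database]
    db_ids = [f"t{i}" if isinstance(r, str) else r.id for i, r in enumerate(database)]

    rng = np.random.default_rng(seed)
    decoys = [klet_shuffle(s, decoy_k, seed=int(rng.integers(2**31))) for s in db_seqs]
    index = _word_index(db_seqs, min_word)
    decoy_index = _word_index(decoys, min_word)
    decoy_ids = [f"decoy_{i}" for i in range(len(decoys))]

    results: list[NoveltyResult] = []
    for qid, query in zip(q_ids, q_seqs):
        cand = _candidates(query, index, min_word)
        best = _best_hit(query, qid, cand, db_seqs, db_ids)
        if best is None:
            results.append(NoveltyResult(qid, None, "no_hit"))
            continue
        decoy_cand = _candidates(query, decoy_index, min_word)
        n_decoy_ge = 0
        for i in decoy_cand:
            d = local_align(query, decoys[i], qid, decoy_ids[i])
            if d is not None and d.score >= best.score:
                n_decoy_ge += 1
        best = AlignmentHit(
            query_id=best.query_id, target_id=best.target_id,
            n_identical=best.n_identical, n_align=best.n_align,
            identity=best.identity, score=best.score, e_value=float(n_decoy_ge),
        )
        if n_decoy_ge > evalue_threshold:
            results.append(NoveltyResult(qid, best, "no_hit"))
        elif best.identity == 100.0:
            results.append(NoveltyResult(qid, best, "identical"))
        else:
            results.append(NoveltyResult(qid, best, "partial"))
    return results


def novelty_fractions(results: list[NoveltyResult]) -> dict[str, float]:
    """Percentages of identical / partial / no-hit queries (0..100 each)."""
    n = len(results)
    if n == 0:
        raise ValueError("no novelty results")
    out = {}
    for cat in ("identical", "partial", "no_hit"):
        out[cat] = 100.0 * sum(r.category == cat for r in results) / n
    return out
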