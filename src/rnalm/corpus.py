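"""Corpus preparation: FASTA I/O, normalization, deduplication, filtering, splitting.

Nucleotide corpora are held internally in DNA alphabet (T, not U); an RNA
rendering toggle (T -> U) is applied only when writing output. Ambiguity codes
from the IUPAC nucleotide set are preserved throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

__all__ = [
    "SequenceRecord",
    "SplitSpec",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "normalize_sequence",
    "deduplicate",
    "filter_by_token_length",
    "split_corpus",
    "write_labels_tsv",
    "read_labels_tsv",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; carries the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with an id and an optional label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SplitSpec:
    """Ordered fractions of a corpus split, e.g. (0.99, 0.01) or (0.6, 0.3, 0.1)."""

    fractions: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(f < 0 for f in fr):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)!r}")


def normalize_sequence(raw: str) -> str:
    """Uppercase, replace U with T, keep IUPAC ambiguity codes.

    Raises ValueError for any character outside the IUPAC nucleotide set plus U.
    """
    if not raw:
        raise ValueError("cannot normalize an empty sequence")
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(
            f"non-IUPAC nucleotide character(s): {sorted(bad)!r}"
        )
    return seq


def _check_fasta_shape(path: str | Path) -> None:
    # SeqIO is permissive about some malformations; pre-scan so errors name a line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            return  # first non-blank line is a header; let SeqIO handle the rest


def read_fasta(path: str | Path, normalize: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into records; optionally normalize (uppercase, U->T)."""
    _check_fasta_shape(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if normalize:
            seq = normalize_sequence(seq)
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, rna: bool = False) -> None:
    """Write records as FASTA wrapped at 60 columns; ``rna=True`` renders T as U."""
    bio = []
    for r in records:
        seq = r.sequence.replace("T", "U") if rna else r.sequence
        bio.append(_BioSeqRecord(Seq(seq), id=r.id, description=""))
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def write_labels_tsv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{r.label or ''}\n")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rid, label = line.rstrip("\n").split("\t")
                out[rid] = label
    return out


# ---------------------------------------------------------------------------
# deduplication

def _word_set(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1)}


def deduplicate(
    records: Sequence[SequenceRecord],
    identity_threshold: float = 0.8,
    min_coverage: float = 0.8,
    min_word: int = 7,
) -> list[SequenceRecord]:
    """Greedy representative clustering by local-alignment identity.

    Each record is compared against already-retained representatives; it is
    discarded as a duplicate when the best Smith-Waterman alignment reaches
    ``identity_threshold`` (matches / alignment columns) while covering at
    least ``min_coverage`` of the shorter sequence — without the coverage
    requirement any chance short perfect local match would count as 100%
    identity. A shared-``min_word``-mer prefilter skips pairs that share no
    seed word. Order-stable given input order.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    from .alignment import local_align  # deferred: avoids import cycle at module load

    retained: list[SequenceRecord] = []
    rep_words: list[set[str]] = []
    for rec in records:
        words = _word_set(rec.sequence, min_word)
        dup = False
        for rep, rw in zip(retained, rep_words):
            if words and rw and not (words & rw):
                continue
            hit = local_align(rec.sequence, rep.sequence)
            if (
                hit is not None
                and hit.identity >= identity_threshold * 100.0
                and hit.n_align >= min_coverage * min(len(rec), len(rep))
            ):
                dup = True
                break
        if not dup:
            retained.append(rec)
            rep_words.append(words)
    return retained


def filter_by_token_length(records, tokenizer, max_tokens: int):
    """Keep records that encode (without EOS) to strictly fewer than ``max_tokens``."""
    return [r for r in records if len(tokenizer.encode(r.sequence)) < max_tokens]


def split_corpus(records: Sequence[SequenceRecord], spec: SplitSpec) -> list[list[SequenceRecord]]:
    """Partition a seeded permutation of ``records`` by largest-remainder rounding.

    Partitions are disjoint, their union is the input, and each size differs
    from n * fraction by less than 1.
    """
    n = len(records)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    # largest-remainder apportionment of n among the fractions
    quotas = [n * f for f in spec.fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    by_frac = sorted(range(len(quotas)), key=lambda i: (quotas[i] - sizes[i]), reverse=True)
    for i in by_frac[:remainder]:
        sizes[i] += 1
    parts: list[list[SequenceRecord]] = []
    start = 0
    for s in sizes:
        parts.append([records[order[i]] for i in range(start, start + s)])
        start += s
    return parts
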