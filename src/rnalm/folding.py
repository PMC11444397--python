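"""Secondary-structure scoring backends.

The built-in backend is a Nussinov-style dynamic program that maximizes
weighted base pairs (GC 3, AU 2, GU 1, arbitrary energy-like units) with a
minimum hairpin loop of 3 unpaired nucleotides; the reported score is the
negated total pair weight, so lower means more stably paired, mirroring the
sign convention of thermodynamic folding energies. Scores are comparable only
within one backend. An adapter wraps the RNAfold program when it is on PATH
for users who want a true nearest-neighbor minimum free energy.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["FoldResult", "NussinovBackend", "ViennaRNABackend", "get_backend", "fold_score"]

MIN_LOOP = 3
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair weights; index 4 = ambiguity code, forced unpaired
_PAIR_W = np.zeros((5, 5), dtype=np.int64)
for _a, _b, _w in (("G", "C", 3), ("A", "T", 2), ("G", "T", 1)):
    _PAIR_W[_BASE_IDX[_a], _BASE_IDX[_b]] = _w
    _PAIR_W[_BASE_IDX[_b], _BASE_IDX[_a]] = _w


@dataclass(frozen=True)
class FoldResult:
    structure: str  # dot-bracket, same length as the sequence
    score: float  # energy-like; lower = more stable; <= 0 for the built-in DP
    backend_id: str


@njit(cache=True)
def _nussinov_fill(idx, wmat):  # pragma: no cover - exercised via fold()
    n = idx.shape[0]
    W = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            if W[i, j - 1] > best:
                best = W[i, j - 1]
            w = wmat[idx[i], idx[j]]
            if w > 0 and W[i + 1, j - 1] + w > best:
                best = W[i + 1, j - 1] + w
            for k in range(i + 1, j):
                v = W[i, k] + W[k + 1, j]
                if v > best:
                    best = v
            W[i, j] = best
    return W


def _traceback(W, idx, n) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if W[i, j] == W[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if W[i, j] == W[i, j - 1]:
            stack.append((i, j - 1))
            continue
        w = _PAIR_W[idx[i], idx[j]]
        if w > 0 and W[i, j] == W[i + 1, j - 1] + w:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if W[i, j] == W[i, k] + W[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return pairs


class NussinovBackend:
    """Weighted base-pair maximization via O(n^3) DP with traceback."""

    backend_id = "nussinov"

    def fold(self, sequence: str) -> FoldResult:
        if not sequence:
            raise ValueError("cannot fold an empty sequence")
        idx = np.array([_BASE_IDX.get(c, 4) for c in sequence.upper()], dtype=np.int64)
        n = len(idx)
        if n <= MIN_LOOP + 1:
            return FoldResult("." * n, 0.0, self.backend_id)
        W = _nussinov_fill(idx, _PAIR_W)
        pairs = _traceback(W, idx, n)
        db = ["."] * n
        for i, j in pairs:
            db[i], db[j] = "(", ")"
        return FoldResult("".join(db), -float(W[0, n - 1]), self.backend_id)


class ViennaRNABackend:
    """Adapter around the RNAfold executable (nearest-neighbor MFE, kcal/mol)."""

    backend_id = "viennarna"

    def __init__(self, executable: str = "RNAfold"):
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable} not found on PATH")
        self.executable = executable

    def fold(self, sequence: str) -> FoldResult:
        if not sequence:
            raise ValueError("cannot fold an empty sequence")
        rna = sequence.upper().replace("T", "U")
        out = subprocess.run(
            [self.executable, "--noPS"], input=rna + "\n", capture_output=True,
            text=True, check=True,
        ).stdout.splitlines()
        line = out[1]
        structure, _, energy = line.partition(" ")
        mfe = float(energy.strip().strip("()"))
        return FoldResult(structure, mfe, self.backend_id)


def get_backend(name: str = "nussinov"):
    if name == "nussinov":
        return NussinovBackend()
    if name == "viennarna":
        return ViennaRNABackend()
    raise ValueError(f"unknown folding backend {name!r}")


def fold_score(sequence: str, backend=None) -> FoldResult:
    """Fold one sequence with the given backend (default: built-in Nussinov)."""
    if backend is None:
        backend = NussinovBackend()
    return backend.fold(sequence)
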