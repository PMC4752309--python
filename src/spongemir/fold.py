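"""Nested base-pair maximisation (Nussinov-style) for hairpin validation.

The discovery stage only needs to know whether an excised candidate folds
into a single clean stem-loop with the mature product on one arm, so a
maximum-cardinality nested pairing over Watson-Crick + GU wobble pairs (N
never pairs) with a minimum hairpin-loop size is sufficient; free-energy
folding is deliberately out of scope.  The O(n^3) fill runs under numba;
traceback is plain Python and deterministic (pair the right end at the
smallest admissible partner before leaving it unpaired).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DataError

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# allowed[x, y]: canonical or wobble pair on the encoded alphabet
_ALLOWED = np.zeros((5, 5), dtype=np.uint8)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _ALLOWED[_a, _b] = 1


@dataclass
class PairTable:
    """A nested secondary structure: partner index per position (-1 = unpaired)."""

    sequence: str
    pairs: list[int]
    dot_bracket: str

    def __post_init__(self) -> None:
        for i, j in enumerate(self.pairs):
            if j >= 0 and (self.pairs[j] != i or j == i):
                raise DataError("pair table is not an involution")

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)

    def n_hairpin_loops(self) -> int:
        """Number of hairpin loops: '(' .. ')' adjacencies in the bracket
        string with only unpaired bases in between."""
        n = 0
        last_open = -1
        for i, c in enumerate(self.dot_bracket):
            if c == "(":
                last_open = i
            elif c == ")":
                if last_open >= 0:
                    n += 1
                last_open = -1
        return n


@njit(cache=False)
def _fill(code: np.ndarray, allowed: np.ndarray, min_loop: int) -> np.ndarray:
    n = code.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i, j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if allowed[code[k], code[j]]:
                    left = m[i, k - 1] if k > i else 0
                    inner = m[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    cand = left + inner + 1
                    if cand > best:
                        best = cand
            m[i, j] = best
    return m


def _traceback(code: np.ndarray, m: np.ndarray, min_loop: int) -> list[int]:
    n = code.shape[0]
    partner = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        # prefer pairing j with its outermost (smallest-index) co-optimal
        # partner, which favours long closing stems; fall through to
        # leaving j unpaired only when no pairing is co-optimal
        paired = False
        for k in range(i, j - min_loop):
            if _ALLOWED[code[k], code[j]]:
                left = m[i, k - 1] if k > i else 0
                inner = m[k + 1, j - 1] if k + 1 <= j - 1 else 0
                if left + inner + 1 == m[i, j]:
                    partner[k], partner[j] = j, k
                    stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return partner


def _to_brackets(pairs: list[int]) -> str:
    return "".join("." if p < 0 else ("(" if p > i else ")")
                   for i, p in enumerate(pairs))


def fold_nussinov(seq: str, min_loop: int = 3) -> PairTable:
    """Fold ``seq`` into a maximum-cardinality nested structure.

    Accepts A/C/G/T/U/N (case-insensitive); N never pairs; every hairpin
    loop encloses at least ``min_loop`` unpaired bases.
    """
    s = seq.upper().replace("U", "T")
    try:
        code = np.array([_ENCODE[c] for c in s], dtype=np.int8)
    except KeyError as exc:
        raise DataError(f"unexpected character in sequence: {exc}") from exc
    if len(s) <= min_loop + 1:
        return PairTable(sequence=s, pairs=[-1] * len(s), dot_bracket="." * len(s))
    m = _fill(code, _ALLOWED, min_loop)
    pairs = _traceback(code, m, min_loop)
    return PairTable(sequence=s, pairs=pairs, dot_bracket=_to_brackets(pairs))


__all__ = ["PairTable", "fold_nussinov"]
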