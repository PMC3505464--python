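"""Nested RNA secondary structure by maximum base pairing.

A Nussinov-style dynamic program over Watson-Crick + G:U pairs with a
minimum hairpin loop of 3 nt.  Maximum base pairing (rather than
free-energy minimisation) keeps the fold deterministic and exactly
checkable against exhaustive enumeration; a thermodynamic folder can be
slotted in behind the same interface without changing downstream
contracts.

The traceback is deterministic: scanning left to right, a position is
paired with the leftmost partner that preserves the optimal count.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._seq import to_rna

MIN_LOOP = 3  # unpaired nt enclosed by the innermost pair

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# pairable[a][b]: Watson-Crick or G:U
_PAIRABLE = np.zeros((4, 4), dtype=np.uint8)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIRABLE[_a, _b] = 1


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str   # RNA
    dotbracket: str
    pair_count: int

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("structure length mismatch")

    def partner(self) -> list[int]:
        """Partner index per position (-1 if unpaired)."""
        part = [-1] * len(self.dotbracket)
        stack: list[int] = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket")
                j = stack.pop()
                part[i], part[j] = j, i
        if stack:
            raise ValueError("unbalanced dot-bracket")
        return part


def _fill_py(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _PAIRABLE[codes[i], codes[k]]:
                    left = N[i + 1, k - 1] if k - 1 > i else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N

try:  # numba gives ~100x on the O(n^3) fill; fall back to pure python
    from numba import njit

    _fill_jit = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover
    _fill_jit = _fill_py


def _encode(seq: str) -> np.ndarray:
    rna = to_rna(seq)
    try:
        return np.array([_BASE_CODE[c] for c in rna], dtype=np.uint8), rna
    except KeyError as exc:
        raise ValueError(f"non-ACGU symbol in sequence: {exc}") from None


def _traceback(N: np.ndarray, codes: np.ndarray) -> list[int]:
    n = len(codes)
    part = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target = N[i, j]
            if target == 0:
                break
            paired = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if _PAIRABLE[codes[i], codes[k]]:
                    left = N[i + 1, k - 1] if k - 1 > i else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    if 1 + left + right == target:
                        part[i], part[k] = k, i
                        if k + 1 <= j:
                            stack.append((k + 1, j))
                        i, j = i + 1, k - 1
                        paired = True
                        break
            if not paired:
                i += 1
    return part


@lru_cache(maxsize=4096)
def fold(seq: str, min_len: int = 1, max_len: int = 300) -> SecondaryStructure:
    """Fold an RNA (or DNA, T read as U) sequence into the nested
    structure with the maximum number of pairs."""
    if not min_len <= len(seq) <= max_len:
        raise ValueError(f"sequence length {len(seq)} outside "
                         f"[{min_len},{max_len}]")
    codes, rna = _encode(seq)
    N = _fill_jit(codes)
    part = _traceback(N, codes)
    db = "".join("(" if (p := part[i]) > i else ")" if p >= 0 else "."
                 for i in range(len(rna)))
    return SecondaryStructure(rna, db, int(N[0, len(rna) - 1]))


def max_pairs_enumerated(seq: str) -> int:
    """Independent oracle: maximum pair count by explicit enumeration
    of all nested pairings (no DP table).  Exponential; use on short
    sequences only."""
    codes, _ = _encode(seq)
    n = len(codes)

    def best(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        i, rest = positions[0], positions[1:]
        top = best(rest)  # i unpaired
        for idx, k in enumerate(rest):
            if k - i > MIN_LOOP and _PAIRABLE[codes[i], codes[k]]:
                inside = tuple(p for p in rest[:idx] if i < p < k)
                outside = tuple(p for p in rest[idx + 1:])
                top = max(top, 1 + best(inside) + best(outside))
        return top

    return best(tuple(range(n)))
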