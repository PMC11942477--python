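"""Base-pair matrices and dot-bracket conversion.

A secondary structure is represented as a set of position pairs (i < j,
0-based) with an L x L binary symmetric matrix view. Ground-truth nested
structures additionally require every position to sit in at most one pair.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable, Set, Tuple

import numpy as np


class PairMatrix:
    """An L x L binary symmetric base-pair contact map."""

    __slots__ = ("L", "pairs")

    def __init__(self, L: int, pairs: Iterable[Tuple[int, int]] = (),
                 nested: bool = True):
        self.L = int(L)
        norm: Set[Tuple[int, int]] = set()
        for i, j in pairs:
            if i == j:
                raise ValueError(f"self-pair at position {i}")
            a, b = (i, j) if i < j else (j, i)
            if a < 0 or b >= self.L:
                raise ValueError(f"pair ({i},{j}) out of range for L={self.L}")
            norm.add((a, b))
        if nested:
            seen: Set[int] = set()
            for a, b in norm:
                if a in seen or b in seen:
                    raise ValueError("position participates in more than one pair")
                seen.update((a, b))
        self.pairs: FrozenSet[Tuple[int, int]] = frozenset(norm)

    def to_matrix(self) -> np.ndarray:
        m = np.zeros((self.L, self.L), dtype=np.float32)
        for i, j in self.pairs:
            m[i, j] = m[j, i] = 1.0
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, threshold: float = 0.5,
                    nested: bool = False) -> "PairMatrix":
        """Pairs where the symmetrized matrix value exceeds ``threshold``."""
        m = np.asarray(matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        sym = 0.5 * (m + m.T)
        ii, jj = np.where(np.triu(sym, 1) > threshold)
        return cls(m.shape[0], zip(ii.tolist(), jj.tolist()), nested=nested)

    def __eq__(self, other) -> bool:
        return (isinstance(other, PairMatrix) and self.L == other.L
                and self.pairs == other.pairs)

    def __hash__(self):
        return hash((self.L, self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __repr__(self) -> str:
        return f"PairMatrix(L={self.L}, n_pairs={len(self.pairs)})"


def parse_dotbracket(db: str) -> PairMatrix:
    """Stack-match a dot-bracket string into a PairMatrix.

    Only the nested ``(``/``)``/``.`` grammar is accepted; pseudoknot
    bracket alphabets ([, {, <) raise ``ValueError``.
    """
    stack = []
    pairs = []
    for pos, ch in enumerate(db):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch == ".":
            continue
        elif ch in "[]{}<>":
            raise ValueError(
                f"pseudoknot bracket {ch!r} at position {pos} is not supported"
            )
        else:
            raise ValueError(f"illegal structure character {ch!r} at {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return PairMatrix(len(db), pairs)


def render_dotbracket(pm: PairMatrix) -> str:
    """Dot-bracket string for a nested PairMatrix (crossing pairs rejected)."""
    chars = ["."] * pm.L
    ordered = sorted(pm.pairs)
    for (i, j), (a, b) in zip(ordered, ordered[1:]):
        if i < a < j < b:
            raise ValueError("crossing pairs cannot be rendered as dot-bracket")
    for i, j in ordered:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def pairs_to_matrix(pairs: Iterable[Tuple[int, int]], L: int) -> PairMatrix:
    return PairMatrix(L, pairs, nested=False)


def matrix_to_pairs(matrix: np.ndarray, threshold: float = 0.5
                    ) -> FrozenSet[Tuple[int, int]]:
    return PairMatrix.from_matrix(matrix, threshold=threshold).pairs
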