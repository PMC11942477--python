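"""RNA sequences and base-pairing rules.

The whole feature system is driven by two small objects: a validated,
normalized base string (:class:`RnaSequence`) and the set of admissible
base pairings with a minimum hairpin-loop constraint (:class:`PairRules`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Tuple

import numpy as np

#: Canonical RNA alphabet used for one-hot encodings, in fixed order.
ALPHABET: Tuple[str, ...] = ("A", "C", "G", "U")

#: Index of each canonical base; N (and any ambiguity code) has no index.
BASE_INDEX: Dict[str, int] = {b: i for i, b in enumerate(ALPHABET)}

# IUPAC ambiguity codes collapse to N: never pairable, all-zero one-hot.
_AMBIGUITY = set("NRYSWKMBDHVX")


class RnaSequence:
    """A validated RNA base string over {A, C, G, U, N}.

    Input is normalized: lowercase is upper-cased, DNA thymine is mapped to
    uracil, and IUPAC ambiguity codes collapse to ``N``. Any other character
    raises ``ValueError``.
    """

    __slots__ = ("bases",)

    def __init__(self, bases: str):
        norm = []
        for ch in bases.upper():
            if ch == "T":
                ch = "U"
            if ch in BASE_INDEX:
                norm.append(ch)
            elif ch in _AMBIGUITY:
                norm.append("N")
            else:
                raise ValueError(f"illegal sequence character {ch!r}")
        if not norm:
            raise ValueError("empty sequence")
        self.bases = "".join(norm)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, i):
        return self.bases[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RnaSequence) and self.bases == other.bases

    def __hash__(self) -> int:
        return hash(self.bases)

    def __repr__(self) -> str:
        s = self.bases if len(self.bases) <= 40 else self.bases[:37] + "..."
        return f"RnaSequence({s!r})"

    def one_hot(self) -> np.ndarray:
        """L x 4 one-hot matrix in A, C, G, U column order; N rows are zero."""
        L = len(self.bases)
        oh = np.zeros((L, 4), dtype=np.float32)
        for p, b in enumerate(self.bases):
            idx = BASE_INDEX.get(b)
            if idx is not None:
                oh[p, idx] = 1.0
        return oh

    def indices(self) -> np.ndarray:
        """Integer base indices (A=0, C=1, G=2, U=3, N=4)."""
        return np.array([BASE_INDEX.get(b, 4) for b in self.bases], dtype=np.int64)

    def pad_or_truncate(self, L: int, mode: str = "head") -> Tuple["RnaSequence", int]:
        """Fit to length ``L``: truncate long sequences, right-pad short ones with N.

        ``mode='head'`` keeps the first L bases; ``mode='center'`` keeps a
        centered window. Returns the fitted sequence and the number of
        real (non-padding) positions.
        """
        b = self.bases
        if len(b) > L:
            if mode == "center":
                start = (len(b) - L) // 2
                b = b[start : start + L]
            else:
                b = b[:L]
            return RnaSequence(b), L
        true_len = len(b)
        return RnaSequence(b + "N" * (L - len(b))), true_len


@dataclass(frozen=True)
class PairRules:
    """Admissible base pairings plus the minimum hairpin-loop length.

    ``pairs`` is an ordered tuple of unordered pairs; the default order is
    Watson-Crick A-U, G-C, then the G-U wobble, and "first rule" means A-U.
    A pair of positions (i, j) is admissible iff the base pair is in
    ``pairs`` and ``|j - i| > min_loop``.
    """

    pairs: Tuple[FrozenSet[str], ...] = (
        frozenset("AU"),
        frozenset("GC"),
        frozenset("GU"),
    )
    min_loop: int = 3

    def __post_init__(self):
        if self.min_loop < 0:
            raise ValueError("min_loop must be nonnegative")

    @property
    def first_rule(self) -> FrozenSet[str]:
        return self.pairs[0]

    def base_pairable(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.pairs

    def _pairable_matrix(self, seq: RnaSequence, rules) -> np.ndarray:
        idx = seq.indices()
        ok = np.zeros((5, 5), dtype=bool)
        for rule in rules:
            members = sorted(rule)
            a, b = (members[0], members[-1])
            ia, ib = BASE_INDEX[a], BASE_INDEX[b]
            ok[ia, ib] = ok[ib, ia] = True
        return ok[idx[:, None], idx[None, :]]

    def admissible(self, seq: RnaSequence) -> np.ndarray:
        """Boolean L x L matrix: True where (i, j) may pair under all rules."""
        L = len(seq)
        pairable = self._pairable_matrix(seq, self.pairs)
        span = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        return pairable & (span > self.min_loop)

    def admissible_first_rule(self, seq: RnaSequence) -> np.ndarray:
        """Boolean L x L admissibility under the first (A-U) rule only."""
        L = len(seq)
        pairable = self._pairable_matrix(seq, self.pairs[:1])
        span = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        return pairable & (span > self.min_loop)

    def complement_of(self, base: str, rng=None) -> str:
        """A partner base admissible with ``base`` (random choice among rules)."""
        partners = [next(iter(p - {base})) if len(p) == 2 else base
                    for p in self.pairs if base in p]
        if not partners:
            raise ValueError(f"base {base!r} has no pairing partner")
        if rng is None:
            return partners[0]
        return partners[int(rng.integers(len(partners)))]


DEFAULT_RULES = PairRules()
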