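"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation's bottom-up vectorized code
paths: the matching oracle is a top-down recursion over "position i is
unpaired or pairs with q", and the interval-count oracles scan every
(interval, position, partner) triple directly.
"""

from functools import lru_cache
from typing import Tuple

import numpy as np

from rnaduet.sequence import PairRules, RnaSequence


def max_matching_oracle(seq: RnaSequence, rules: PairRules, i: int, j: int) -> int:
    """Maximum non-crossing matching size in [i..j] by top-down recursion."""
    adm = rules.admissible(seq)

    @lru_cache(maxsize=None)
    def rec(a: int, b: int) -> int:
        if a >= b:
            return 0
        best = rec(a + 1, b)
        for q in range(a + 1, b + 1):
            if adm[a, q]:
                best = max(best, 1 + rec(a + 1, q - 1) + rec(q + 1, b))
        return best

    return rec(i, j)


def srs_count_oracle(seq: RnaSequence, rules: PairRules, base: str,
                     i: int, j: int, threshold: int = 2) -> int:
    """Direct count of base-``base`` positions in [i..j] with >= threshold
    admissible partners inside [i..j]."""
    adm = rules.admissible(seq)
    count = 0
    for p in range(i, j + 1):
        if seq[p] != base:
            continue
        partners = sum(1 for q in range(i, j + 1) if adm[p, q])
        if partners >= threshold:
            count += 1
    return count


def bms_count_oracle(seq: RnaSequence, rules: PairRules, base: str,
                     i: int, j: int) -> int:
    """Direct count under the first (A-U) pairing rule only, threshold 1."""
    adm = rules.admissible_first_rule(seq)
    count = 0
    for p in range(i, j + 1):
        if seq[p] != base:
            continue
        if any(adm[p, q] for q in range(i, j + 1)):
            count += 1
    return count


def random_sequence(rng: np.random.Generator, L: int,
                    alphabet: str = "ACGU") -> RnaSequence:
    return RnaSequence("".join(alphabet[k] for k in rng.integers(0, len(alphabet), L)))
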