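"""k-mer tokenization of RNA/DNA sequences.

A sequence of length L yields the L - k + 1 overlapping k-mers, wrapped in
CLS/SEP specials for a total of L - k + 3 tokens. DNA input is served by
the same vocabulary because T is mapped to U during sequence
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .sequence import ALPHABET, RnaSequence

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
SPECIALS: Tuple[str, ...] = (PAD, UNK, CLS, SEP)


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token stream: [CLS], the k-mers, [SEP]."""

    tokens: Tuple[str, ...]
    k: int

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_kmers(seq: RnaSequence, k: int = 3) -> TokenSequence:
    """Merge every k consecutive bases into a token; add CLS/SEP.

    Raises ``ValueError`` when the sequence is shorter than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence length {L} shorter than k={k}")
    kmers = [seq.bases[i : i + k] for i in range(L - k + 1)]
    return TokenSequence((CLS, *kmers, SEP), k)


class KmerVocab:
    """Deterministic vocabulary: 4 specials + all |alphabet|^k k-mers.

    Ids are assigned by position: PAD=0, UNK=1, CLS=2, SEP=3, then the
    k-mers in lexicographic order.
    """

    def __init__(self, k: int, alphabet: Sequence[str] = ALPHABET):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        kmers = ["".join(p) for p in product(sorted(alphabet), repeat=k)]
        self.tokens: List[str] = list(SPECIALS) + kmers
        self.token_to_id: Dict[str, int] = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def encode(self, ts: TokenSequence, pad_to: int = 0) -> np.ndarray:
        """Token ids; unknown k-mers (e.g. containing N) map to UNK."""
        ids = [self.token_to_id.get(t, self.unk_id) for t in ts.tokens]
        if pad_to and len(ids) < pad_to:
            ids.extend([self.pad_id] * (pad_to - len(ids)))
        return np.asarray(ids, dtype=np.int64)

    def decode_sequence(self, ids: Sequence[int]) -> str:
        """Reconstruct the base string from k-mer token ids (specials skipped)."""
        kmers = [self.tokens[i] for i in ids
                 if self.tokens[int(i)] not in SPECIALS]
        if not kmers:
            return ""
        return kmers[0] + "".join(km[-1] for km in kmers[1:])

    def save(self, path) -> None:
        with open(path, "w") as f:
            f.write("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "KmerVocab":
        with open(path) as f:
            tokens = [line.strip() for line in f if line.strip()]
        k = len(tokens[-1])
        vocab = cls.__new__(cls)
        vocab.k = k
        vocab.tokens = tokens
        vocab.token_to_id = {t: i for i, t in enumerate(tokens)}
        return vocab
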