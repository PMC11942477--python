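"""Seeded synthetic fixtures: sequences, nested structures, labeled tasks.

These generators stand in for real corpora so that every component is
testable offline. They emulate three study settings:

* ``structure`` — sequences with a known nested secondary structure,
  sampled by a recursive pair-or-advance process under the minimum-loop
  constraint, with admissible bases written onto the paired positions;
* ``classification`` — balanced classes distinguished by a planted motif
  with per-base mutation noise on a uniform background;
* ``interaction`` — a binary protein-binding-style task where positives
  carry the motif inside the stem of a planted hairpin (emulating
  double-strand-preferring binders) and negatives lack the motif.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .sequence import ALPHABET, DEFAULT_RULES, PairRules, RnaSequence
from .structure import PairMatrix

# Pair-type mix used when writing bases onto paired positions.
_PAIR_CHOICES = ("GC", "AU", "GU")
_PAIR_WEIGHTS = (2.0, 2.0, 1.0)  # G-C : A-U : G-U = 2 : 2 : 1


@dataclass(frozen=True)
class LabeledRecord:
    id: str
    seq: RnaSequence
    label: str
    structure: Optional[PairMatrix] = None


@dataclass
class SynthSpec:
    """Parameters of a synthetic dataset.

    ``motifs`` maps class labels to planted motif strings; ``noise`` is the
    per-base mutation probability applied to planted motifs.
    """

    n_records: int = 400
    L: int = 112
    seed: int = 0
    task: str = "classification"
    motifs: Sequence[Tuple[str, str]] = (("pos", "GGCCGG"), ("neg", "AUAUAU"))
    noise: float = 0.05
    neg_ratio: int = 2  # interaction task: negatives per positive

    def __post_init__(self):
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must be in [0, 1)")
        if self.task not in {"structure", "classification", "interaction"}:
            raise ValueError(f"unknown task {self.task!r}")
        for _, m in self.motifs:
            if len(m) > self.L:
                raise ValueError(f"motif {m!r} longer than L={self.L}")


def random_structure(L: int, h: int = 3, seed: int = 0,
                     pair_prob: float = 0.4,
                     rules: PairRules = DEFAULT_RULES,
                     rng: Optional[np.random.Generator] = None
                     ) -> Tuple[RnaSequence, PairMatrix]:
    """A random valid nested structure and a compatible sequence.

    Interval (i, j) either pairs i with a uniformly chosen q > i + h
    (probability ``pair_prob`` when feasible), recursing inside and to the
    right, or leaves i unpaired. Paired positions receive admissible bases
    (G-C : A-U : G-U drawn 2:2:1), unpaired positions uniform bases.
    """
    if L < h + 2:
        raise ValueError(f"L={L} cannot host a pair with min_loop={h}")
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs: List[Tuple[int, int]] = []
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        if j - i > h and rng.random() < pair_prob:
            q = int(rng.integers(i + h + 1, j + 1))
            pairs.append((i, q))
            stack.append((i + 1, q - 1))
            stack.append((q + 1, j))
        else:
            stack.append((i + 1, j))
    bases = [""] * L
    w = np.asarray(_PAIR_WEIGHTS) / sum(_PAIR_WEIGHTS)
    for i, j in pairs:
        kind = _PAIR_CHOICES[int(rng.choice(len(_PAIR_CHOICES), p=w))]
        a, b = kind[0], kind[1]
        if rng.random() < 0.5:
            a, b = b, a
        bases[i], bases[j] = a, b
    for p in range(L):
        if not bases[p]:
            bases[p] = ALPHABET[int(rng.integers(4))]
    return RnaSequence("".join(bases)), PairMatrix(L, pairs)


def _mutate(motif: str, noise: float, rng: np.random.Generator) -> str:
    out = []
    for ch in motif:
        if noise > 0 and rng.random() < noise:
            out.append(ALPHABET[int(rng.integers(4))])
        else:
            out.append(ch)
    return "".join(out)


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=n))


def motif_dataset(spec: SynthSpec) -> List[LabeledRecord]:
    """Balanced classification dataset with one planted motif per class."""
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.motifs)
    counts = [spec.n_records // n_classes] * n_classes
    for c in range(spec.n_records % n_classes):
        counts[c] += 1
    records: List[LabeledRecord] = []
    order = []
    for c, n in enumerate(counts):
        order.extend([c] * n)
    rng.shuffle(order)
    all_motifs = [m for _, m in spec.motifs]
    for n, c in enumerate(order):
        label, motif = spec.motifs[c]
        # the planted motif is the only class signal: resample backgrounds
        # that contain any class motif by chance
        while True:
            bg = _random_bases(spec.L, rng)
            if not any(m in bg for m in all_motifs):
                break
        planted = _mutate(motif, spec.noise, rng)
        start = int(rng.integers(0, spec.L - len(motif) + 1))
        seq = bg[:start] + planted + bg[start + len(planted):]
        records.append(LabeledRecord(f"rec{n:05d}", RnaSequence(seq), label))
    return records


def _hairpin_with_motif(L: int, motif: str, h: int, noise: float,
                        rng: np.random.Generator
                        ) -> Tuple[RnaSequence, PairMatrix]:
    """Background sequence with a hairpin whose 5' stem strand is the motif."""
    s = len(motif)
    loop = h + 1
    span = 2 * s + loop
    if span > L:
        raise ValueError(f"motif {motif!r} too long for a stem within L={L}")
    start = int(rng.integers(0, L - span + 1))
    stem5 = _mutate(motif, noise, rng)
    stem3 = "".join(DEFAULT_RULES.complement_of(b, rng) if b != "N" else "N"
                    for b in reversed(stem5))
    bg = _random_bases(L, rng)
    seq = (bg[:start] + stem5 + _random_bases(loop, rng) + stem3
           + bg[start + span:])
    pairs = [(start + t, start + span - 1 - t) for t in range(s)]
    return RnaSequence(seq), PairMatrix(L, pairs)


def interaction_dataset(spec: SynthSpec) -> List[LabeledRecord]:
    """Binary interaction task: motif-in-stem positives, motif-free negatives."""
    rng = np.random.default_rng(spec.seed)
    label, motif = spec.motifs[0]
    n_pos = spec.n_records // (1 + spec.neg_ratio)
    n_neg = spec.n_records - n_pos
    records: List[LabeledRecord] = []
    for n in range(n_pos):
        seq, pm = _hairpin_with_motif(spec.L, motif, DEFAULT_RULES.min_loop,
                                      spec.noise, rng)
        records.append(LabeledRecord(f"pos{n:05d}", seq, "1", pm))
    for n in range(n_neg):
        while True:
            bases = _random_bases(spec.L, rng)
            if motif not in bases:
                break
        records.append(LabeledRecord(f"neg{n:05d}", RnaSequence(bases), "0"))
    idx = rng.permutation(len(records))
    return [records[i] for i in idx]


def structure_dataset(n: int, L: int, seed: int = 0, h: int = 3,
                      pair_prob: float = 0.4) -> List[LabeledRecord]:
    """Records carrying random nested structures (for the structure task)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq, pm = random_structure(L, h=h, rng=rng, pair_prob=pair_prob)
        out.append(LabeledRecord(f"struct{i:05d}", seq, "structure", pm))
    return out
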