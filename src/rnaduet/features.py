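"""The 24-channel structural "vision" feature stack.

Every channel is an L x L matrix computed from the raw sequence alone:

* **LPSS** (longest possible secondary structure): for every fragment
  [i..j], the maximum number of mutually non-crossing admissible base
  pairs that can be formed inside it — the classic maximum-matching
  dynamic programme with a minimum hairpin-loop constraint.
* **SRS** (sequence repeat structure, 5 maps): per fragment, how many
  bases of each type could pair with *two or more* distinct partners
  inside the fragment (pairing ambiguity), plus an aggregate map.
* **BMS** (base missing structure, 5 maps): per fragment, how many bases
  of each type have at least one partner inside the fragment under the
  first pairing rule (A-U) only, plus an aggregate map.
* **RCM** (RNA coding matrix): a soft pairing-propensity score — the
  pair-type weight at (i, j) plus Gaussian-decayed contributions from
  stacked neighbours (i∓t, j±t) as long as they remain admissible.
* **Spatial / Manhattan distances**: Euclidean distance between
  binary-position + one-hot codes, and the L1 distance between one-hot
  codes.
* **BPS** (base pairing signature, 10 maps): ordered base-identity
  outer products (the Kronecker product of the one-hot encoding with
  itself gives 16 channels; the 6 reversed hetero labels are transposes
  of kept channels and are dropped).

Stacked in a fixed registry order this yields 24 x L x L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil, log2
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .sequence import ALPHABET, BASE_INDEX, DEFAULT_RULES, PairRules, RnaSequence

# SRS/BMS per-base channel order follows the A, U, C, G presentation order.
SRS_BASE_ORDER: Tuple[str, ...] = ("A", "U", "C", "G")

#: Kept ordered BPS labels: (b1, b2) with b1 <= b2 in A,C,G,U alphabet order.
BPS_LABELS: Tuple[str, ...] = (
    "AA", "AC", "AG", "AU", "CC", "CG", "CU", "GG", "GU", "UU",
)

#: Stable channel registry of the assembled 24-channel stack.
REGISTRY: Tuple[str, ...] = (
    ("LPSS", "RCM")
    + tuple(f"SRS_{b}" for b in SRS_BASE_ORDER) + ("SRS_ALL",)
    + tuple(f"BMS_{b}" for b in SRS_BASE_ORDER) + ("BMS_ALL",)
    + ("SPATIAL", "MANHATTAN")
    + tuple(f"BPS_{l}" for l in BPS_LABELS)
)

DEFAULT_RCM_WEIGHTS: Dict[frozenset, float] = {
    frozenset("AU"): 2.0,
    frozenset("GC"): 3.0,
    frozenset("GU"): 0.8,
}


try:  # optional JIT acceleration; the numpy paths are the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@_njit(cache=True)
def _lpss_kernel(P: np.ndarray) -> np.ndarray:  # pragma: no cover - jitted
    L = P.shape[0]
    M = np.zeros((L, L), dtype=np.int32)
    for s in range(1, L):
        for i in range(L - s):
            j = i + s
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            cand = M[i + 1, j - 1] + P[i, j]
            if cand > best:
                best = cand
            for t in range(1, s):
                cand = M[i, i + t] + M[i + t + 1, j]
                if cand > best:
                    best = cand
            M[i, j] = best
    return M


def lpss_matrix(seq: RnaSequence, rules: PairRules = DEFAULT_RULES) -> np.ndarray:
    """Maximum non-crossing matching size for every fragment [i..j].

    Entry (i, j) with i < j is the largest number of admissible,
    mutually non-crossing base pairs formable within positions i..j;
    the matrix is mirrored to be symmetric with a zero diagonal.
    """
    L = len(seq)
    P = rules.admissible(seq).astype(np.int32)
    if _HAVE_NUMBA:
        M = _lpss_kernel(P)
        return (M + M.T).astype(np.float32)
    M = np.zeros((L, L), dtype=np.int32)
    # Bottom-up over spans; each span is vectorized over the diagonal.
    for s in range(1, L):
        i = np.arange(L - s)
        j = i + s
        best = np.maximum(M[i + 1, j], M[i, j - 1])
        best = np.maximum(best, M[i + 1, j - 1] + P[i, j])
        for t in range(1, s):  # bifurcation: split [i..j] at i+t
            np.maximum(best, M[i, i + t] + M[i + t + 1, j], out=best)
        M[i, j] = best
    return (M + M.T).astype(np.float32)


@_njit(cache=True)
def _interval_counts_kernel(adm: np.ndarray, codes: np.ndarray,
                            threshold: int) -> np.ndarray:  # pragma: no cover
    L = adm.shape[0]
    out = np.zeros((4, L, L), dtype=np.float32)
    cnt = np.zeros(L, dtype=np.int32)
    met = np.zeros(4, dtype=np.int32)
    for i in range(L):
        for p in range(i, L):
            cnt[p] = 0
        for c in range(4):
            met[c] = 0
        for j in range(i + 1, L):
            # position j enters the interval: each earlier q gains j as a
            # partner where admissible (adm is symmetric), and j itself
            # starts with its partner count inside [i..j]
            cj = 0
            for q in range(i, j):
                if adm[q, j]:
                    cj += 1
                    cnt[q] += 1
                    if cnt[q] == threshold and codes[q] < 4:
                        met[codes[q]] += 1
            cnt[j] = cj
            if cj >= threshold and codes[j] < 4:
                met[codes[j]] += 1
            for c in range(4):
                out[c, i, j] = met[c]
                out[c, j, i] = met[c]
    return out


def _interval_threshold_counts(adm: np.ndarray, base_mask: Dict[str, np.ndarray],
                               threshold: int) -> np.ndarray:
    """Shared SRS/BMS kernel.

    For every interval [i..j] and base type b, counts positions p in [i..j]
    with base b whose number of admissible partners inside [i..j] reaches
    ``threshold``. Returns a (4, L, L) symmetric stack in SRS_BASE_ORDER.
    """
    L = adm.shape[0]
    if _HAVE_NUMBA:
        order = {b: c for c, b in enumerate(SRS_BASE_ORDER)}
        codes = np.full(L, 4, dtype=np.int8)
        for b, mask in base_mask.items():
            codes[mask] = order[b]
        return _interval_counts_kernel(adm.astype(np.int8), codes,
                                       threshold)
    C = np.zeros((L, L + 1), dtype=np.int32)
    np.cumsum(adm.astype(np.int32), axis=1, out=C[:, 1:])
    out = np.zeros((4, L, L), dtype=np.float32)
    masks = [base_mask[b] for b in SRS_BASE_ORDER]
    for i in range(L):
        # cnt[r, c] = number of partners of position p=i+r inside [i, i+c]
        cnt = C[i:, i + 1:] - C[i:, i][:, None]
        meets = cnt >= threshold
        for ch, m in enumerate(masks):
            sel = meets & m[i:, None]
            # entry (i, j=i+c) sums rows r<=c: cumulate down then take diagonal
            out[ch, i, i:] = np.diagonal(np.cumsum(sel, axis=0))
    # mirror upper triangle
    for ch in range(4):
        iu = np.triu(out[ch], 1)
        out[ch] = iu + iu.T
    return out


def _base_masks(seq: RnaSequence) -> Dict[str, np.ndarray]:
    arr = np.frombuffer(seq.bases.encode(), dtype="S1").astype("U1")
    return {b: arr == b for b in ALPHABET}


def srs_maps(seq: RnaSequence, rules: PairRules = DEFAULT_RULES) -> np.ndarray:
    """Sequence-repeat-structure maps: (5, L, L).

    Channels 0-3 (A, U, C, G order) count bases of that type with >= 2
    admissible partners inside the fragment; channel 4 is their sum.
    """
    per = _interval_threshold_counts(rules.admissible(seq), _base_masks(seq), 2)
    return np.concatenate([per, per.sum(axis=0, keepdims=True)], axis=0)


def bms_maps(seq: RnaSequence, rules: PairRules = DEFAULT_RULES) -> np.ndarray:
    """Base-missing-structure maps: (5, L, L).

    Channels 0-3 (A, U, C, G order) count bases of that type with >= 1
    partner inside the fragment under the first (A-U) rule only;
    channel 4 is their sum.
    """
    per = _interval_threshold_counts(
        rules.admissible_first_rule(seq), _base_masks(seq), 1
    )
    return np.concatenate([per, per.sum(axis=0, keepdims=True)], axis=0)


def rcm_matrix(seq: RnaSequence, rules: PairRules = DEFAULT_RULES,
               sigma: float = 1.0,
               weights: Optional[Dict] = None) -> np.ndarray:
    """Soft pairing-propensity matrix with Gaussian-decayed stacking context.

    For an admissible (i, j), the score accumulates
    ``exp(-t^2 / (2 sigma^2)) * weight(i-t, j+t)`` outward over t = 0, 1, ...
    while the offset pair stays in range and admissible (stopping at the
    first failure), plus the analogous inward accumulation over
    (i+t, j-t) for t >= 1. Inadmissible (i, j) score 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if weights is None:
        weights = DEFAULT_RCM_WEIGHTS
    L = len(seq)
    P = rules.admissible(seq)
    idx = seq.indices()
    wtab = np.zeros((5, 5), dtype=np.float64)
    for pair, w in weights.items():
        members = sorted(pair)
        a, b = members[0], members[-1]
        ia, ib = BASE_INDEX[a], BASE_INDEX[b]
        wtab[ia, ib] = wtab[ib, ia] = w
    W = wtab[idx[:, None], idx[None, :]]

    upper = np.triu(np.ones((L, L), dtype=bool), 1)
    R = np.zeros((L, L), dtype=np.float64)

    # outward extensions: (i - t, j + t)
    alive = P & upper
    R[alive] += W[alive]
    for t in range(1, L):
        decay = float(np.exp(-(t * t) / (2.0 * sigma * sigma)))
        shiftP = np.zeros((L, L), dtype=bool)
        shiftW = np.zeros((L, L), dtype=np.float64)
        shiftP[t:, : L - t] = P[: L - t, t:]
        shiftW[t:, : L - t] = W[: L - t, t:]
        alive = alive & shiftP
        if not alive.any():
            break
        R[alive] += decay * shiftW[alive]

    # inward extensions: (i + t, j - t), t >= 1
    alive = P & upper
    for t in range(1, L):
        decay = float(np.exp(-(t * t) / (2.0 * sigma * sigma)))
        shiftP = np.zeros((L, L), dtype=bool)
        shiftW = np.zeros((L, L), dtype=np.float64)
        shiftP[: L - t, t:] = P[t:, : L - t]
        shiftW[: L - t, t:] = W[t:, : L - t]
        # the inward pair must stay properly ordered: i + t < j - t
        order = (np.arange(L)[None, :] - np.arange(L)[:, None]) > 2 * t
        alive = alive & shiftP & order
        if not alive.any():
            break
        R[alive] += decay * shiftW[alive]

    return (R + R.T).astype(np.float32)


def spatial_distance(seq: RnaSequence) -> np.ndarray:
    """Euclidean distance between binary-position + one-hot base codes.

    Position p (0-based) is encoded as ``B = ceil(log2(max(L, 2)))`` bits,
    most-significant first, concatenated with the 4-slot one-hot of its
    base (zeros for N).
    """
    L = len(seq)
    B = int(ceil(log2(max(L, 2))))
    pos = np.arange(L)
    bits = ((pos[:, None] >> np.arange(B - 1, -1, -1)[None, :]) & 1).astype(np.float64)
    code = np.concatenate([bits, seq.one_hot().astype(np.float64)], axis=1)
    if L == 1:
        return np.zeros((1, 1), dtype=np.float32)
    return squareform(pdist(code, metric="euclidean")).astype(np.float32)


def manhattan_distance(seq: RnaSequence) -> np.ndarray:
    """L1 distance between one-hot base encodings (N encodes as zeros)."""
    L = len(seq)
    if L == 1:
        return np.zeros((1, 1), dtype=np.float32)
    oh = seq.one_hot().astype(np.float64)
    return squareform(pdist(oh, metric="cityblock")).astype(np.float32)


def bps_tensor(seq: RnaSequence) -> np.ndarray:
    """Base pairing signature: (10, L, L) ordered base-identity channels.

    The full Kronecker product of the one-hot encoding with itself gives 16
    ordered channels (b1, b2): entry (i, j) = 1 iff base i is b1 and base j
    is b2. A reversed hetero label is the transpose of its kept partner, so
    the 6 channels with b1 > b2 are redundant and dropped, leaving the 10
    labels in :data:`BPS_LABELS`.
    """
    oh = seq.one_hot()
    out = np.empty((len(BPS_LABELS), len(seq), len(seq)), dtype=np.float32)
    for c, label in enumerate(BPS_LABELS):
        i1, i2 = BASE_INDEX[label[0]], BASE_INDEX[label[1]]
        out[c] = np.outer(oh[:, i1], oh[:, i2])
    return out


def bps_tensor_full(seq: RnaSequence) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """All 16 ordered BPS channels (before redundancy removal) with labels."""
    oh = seq.one_hot()
    labels = tuple(b1 + b2 for b1 in ALPHABET for b2 in ALPHABET)
    out = np.empty((16, len(seq), len(seq)), dtype=np.float32)
    for c, label in enumerate(labels):
        i1, i2 = BASE_INDEX[label[0]], BASE_INDEX[label[1]]
        out[c] = np.outer(oh[:, i1], oh[:, i2])
    return out, labels


@dataclass
class FeatureStack:
    """A 24 x L x L float32 channel tensor with a named channel registry."""

    data: np.ndarray
    registry: Tuple[str, ...] = REGISTRY
    params: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[0] != len(self.registry):
            raise ValueError(
                f"expected ({len(self.registry)}, L, L) data, got {self.data.shape}"
            )
        self.data = self.data.astype(np.float32, copy=False)

    @property
    def L(self) -> int:
        return self.data.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.registry.index(name)]


def build_feature_stack(seq: RnaSequence, rules: PairRules = DEFAULT_RULES,
                        normalize: bool = True, sigma: float = 1.0,
                        rcm_weights: Optional[Dict] = None,
                        valid_length: Optional[int] = None) -> FeatureStack:
    """Assemble the full 24-channel stack in registry order.

    With ``normalize`` on, every non-BPS channel is divided by its own
    maximum (identically-zero channels are left untouched); BPS channels
    are already binary. ``valid_length`` zeroes the rows/columns of padded
    positions in every channel.
    """
    parts = [
        lpss_matrix(seq, rules)[None],
        rcm_matrix(seq, rules, sigma=sigma, weights=rcm_weights)[None],
        srs_maps(seq, rules),
        bms_maps(seq, rules),
        spatial_distance(seq)[None],
        manhattan_distance(seq)[None],
        bps_tensor(seq),
    ]
    stack = np.concatenate(parts, axis=0).astype(np.float32)
    n_scalar = 14  # channels before the binary BPS block
    if valid_length is not None and valid_length < len(seq):
        stack[:, valid_length:, :] = 0.0
        stack[:, :, valid_length:] = 0.0
    if normalize:
        for c in range(n_scalar):
            mx = stack[c].max()
            if mx > 0:
                stack[c] /= mx
    params = {
        "min_loop": rules.min_loop,
        "sigma": sigma,
        "weights": {"".join(sorted(k)): v
                    for k, v in (rcm_weights or DEFAULT_RCM_WEIGHTS).items()},
        "normalize": bool(normalize),
    }
    return FeatureStack(stack, REGISTRY, params)


def featurize_records(records: Sequence[Tuple[str, RnaSequence]], L: int,
                      rules: PairRules = DEFAULT_RULES, normalize: bool = True,
                      crop: str = "head", **kwargs) -> Tuple[np.ndarray, List[str]]:
    """Featurize many records at a fixed length.

    Long sequences are cropped, short ones right-padded with N; padded
    rows/columns are zeroed. Returns (N, 24, L, L) float32 and the ids.
    """
    feats = np.empty((len(records), len(REGISTRY), L, L), dtype=np.float32)
    ids = []
    for n, (rid, seq) in enumerate(records):
        fitted, true_len = seq.pad_or_truncate(L, mode=crop)
        fs = build_feature_stack(fitted, rules, normalize=normalize,
                                 valid_length=true_len, **kwargs)
        feats[n] = fs.data
        ids.append(rid)
    return feats, ids


def save_hdf5(path, features: np.ndarray, ids: Sequence[str],
              params: Optional[Dict] = None) -> None:
    """Write an (N, 24, L, L) feature container with ids and parameters."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features.astype(np.float32))
        f.create_dataset("ids", data=np.array(ids, dtype=h5py.string_dtype()))
        f.attrs["registry"] = json.dumps(list(REGISTRY))
        f.attrs["params"] = json.dumps(params or {})


def load_hdf5(path) -> Tuple[np.ndarray, List[str], Tuple[str, ...], Dict]:
    import h5py

    with h5py.File(path, "r") as f:
        feats = f["features"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][...]]
        registry = tuple(json.loads(f.attrs["registry"]))
        params = json.loads(f.attrs["params"])
    return feats, ids, registry, params
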