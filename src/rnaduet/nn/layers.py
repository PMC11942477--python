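"""Neural-network layers built on the autodiff engine.

Includes the generic pieces (Linear, LayerNorm, Embedding, Dropout,
multi-head attention, MLP) and the vision-specific blocks (patch
embedding, window/shifted-window attention blocks, patch merging, and the
pixel-shuffle upsampler used by the structure decoder).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .autograd import Tensor, as_tensor, gather_rows

_NEG_INF = -1e9


class Module:
    """Minimal parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out: Dict[str, Tensor] = {}

        def visit(key, value):
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for n, item in enumerate(value):
                    visit(f"{key}.{n}", item)

        for name, value in vars(self).items():
            visit(f"{prefix}{name}", value)
        return out

    def parameters(self) -> List[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, init_scale: float = 1.0):
        self.weight = _param(rng, (d_in, d_out),
                             init_scale * np.sqrt(2.0 / (d_in + d_out)))
        self.bias = (Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)
                     if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layernorm(self.gamma, self.beta, eps=self._eps)


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = _param(rng, (n, dim), 0.02)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return gather_rows(self.weight, idx)


class Dropout(Module):
    """Inverted dropout; a no-op unless ``train=True`` and p > 0."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, train: bool = False,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
        if not train or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(np.float32))


class MultiHeadAttention(Module):
    """Scaled dot-product attention, shared by SA (q is kv) and CA.

    Inputs are (..., T, D); an optional additive mask broadcastable to
    (..., heads, Tq, Tk) is applied to the logits before softmax.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.dk = dim, heads, dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        # damped init keeps residual branches near-identity at start
        self.wo = Linear(dim, dim, rng, init_scale=0.25)
        self._last_attn: Optional[np.ndarray] = None

    def _split(self, x: Tensor) -> Tensor:
        *lead, T, _ = x.shape
        return (x.reshape(*lead, T, self.heads, self.dk)
                .swapaxes(-3, -2))  # (..., heads, T, dk)

    def __call__(self, q_src: Tensor, kv_src: Optional[Tensor] = None,
                 mask: Optional[np.ndarray] = None,
                 bias: Optional[Tensor] = None) -> Tensor:
        if kv_src is None:
            kv_src = q_src
        if q_src.shape[-1] != self.dim or kv_src.shape[-1] != self.dim:
            raise ValueError("feature dimension mismatch")
        q = self._split(self.wq(q_src))
        k = self._split(self.wk(kv_src))
        v = self._split(self.wv(kv_src))
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / float(np.sqrt(self.dk)))
        if bias is not None:
            logits = logits + bias
        if mask is not None:
            logits = logits + as_tensor(mask.astype(np.float32))
        attn = logits.softmax(axis=-1)
        self._last_attn = attn.data
        out = attn @ v  # (..., heads, Tq, dk)
        *lead, H, T, dk = out.shape
        merged = out.swapaxes(-3, -2).reshape(*lead, T, H * dk)
        return self.wo(merged)


class RelPosBias2D(Module):
    """Learned relative-position bias for window attention.

    One scalar per head per 2-D offset within a window; indexed into a
    (heads, w*w, w*w) bias added to the attention logits.
    """

    def __init__(self, window: int, heads: int):
        w = window
        # distance-penalty initialization (geometric per-head slopes), as
        # in the 1-D case; the table remains trainable
        dy, dx = np.meshgrid(np.arange(-(w - 1), w), np.arange(-(w - 1), w),
                             indexing="ij")
        dist = np.sqrt(dy ** 2 + dx ** 2).reshape(-1)
        slopes = 2.0 ** (-8.0 * (np.arange(heads) + 1) / heads)
        init = (-slopes[None, :] * dist[:, None]).astype(np.float32)
        self.table = Tensor(init, requires_grad=True)
        coords = np.stack(np.meshgrid(np.arange(w), np.arange(w),
                                      indexing="ij")).reshape(2, -1)
        rel = coords[:, :, None] - coords[:, None, :] + (w - 1)
        self._index = (rel[0] * (2 * w - 1) + rel[1]).reshape(-1)
        self._shape = (w * w, w * w)
        self.heads = heads

    def __call__(self) -> Tensor:
        bias = gather_rows(self.table, self._index)  # (w^4, heads)
        return bias.reshape(*self._shape, self.heads).transpose(2, 0, 1)


class RelPosBias1D(Module):
    """Learned relative-position bias over clipped 1-D token offsets.

    Initialized as a per-head distance penalty (geometric slopes, as in
    attention-with-linear-biases): early heads start strongly local and
    later heads near-global, which makes short-range token conjunctions
    learnable quickly; the table remains fully trainable.
    """

    def __init__(self, max_offset: int, heads: int):
        self.max_offset = max_offset
        offsets = np.abs(np.arange(-max_offset, max_offset + 1))
        slopes = 2.0 ** (-8.0 * (np.arange(heads) + 1) / heads)
        init = (-slopes[None, :] * offsets[:, None]).astype(np.float32)
        self.table = Tensor(init, requires_grad=True)
        self.heads = heads

    def __call__(self, T: int) -> Tensor:
        off = np.arange(T)[:, None] - np.arange(T)[None, :]
        idx = np.clip(off, -self.max_offset, self.max_offset) + self.max_offset
        bias = gather_rows(self.table, idx.reshape(-1))
        return bias.reshape(T, T, self.heads).transpose(2, 0, 1)


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng, init_scale=0.25)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerLayer(Module):
    """Pre-LN transformer encoder layer (attention + MLP, residual)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0, dropout: float = 0.0,
                 max_rel_offset: int = 32):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.rel_bias = RelPosBias1D(max_rel_offset, heads)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, mask: Optional[np.ndarray] = None,
                 train: bool = False, rng=None) -> Tensor:
        bias = self.rel_bias(x.shape[-2])
        x = x + self.drop(self.attn(self.norm1(x), mask=mask, bias=bias),
                          train, rng)
        return x + self.drop(self.mlp(self.norm2(x)), train, rng)


# ---------------------------------------------------------------------
# vision blocks
# ---------------------------------------------------------------------

def window_partition(x: Tensor, w: int) -> Tensor:
    """(B, H, W, C) -> (B * nH * nW, w*w, C) for H, W divisible by w."""
    B, H, W, C = x.shape
    x = x.reshape(B, H // w, w, W // w, w, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B * (H // w) * (W // w), w * w, C)


def window_reverse(x: Tensor, w: int, B: int, H: int, W: int) -> Tensor:
    C = x.shape[-1]
    x = x.reshape(B, H // w, W // w, w, w, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, H, W, C)


def shifted_window_mask(H: int, W: int, w: int, shift: int) -> np.ndarray:
    """Additive attention mask for shifted windows (standard region trick)."""
    img = np.zeros((H, W), dtype=np.int64)
    region = 0
    for hs in (slice(0, H - w), slice(H - w, H - shift), slice(H - shift, H)):
        for ws in (slice(0, W - w), slice(W - w, W - shift), slice(W - shift, W)):
            img[hs, ws] = region
            region += 1
    img = np.roll(img, (-shift, -shift), axis=(0, 1))
    wins = img.reshape(H // w, w, W // w, w).transpose(0, 2, 1, 3)
    wins = wins.reshape(-1, w * w)
    diff = wins[:, :, None] != wins[:, None, :]
    # (nWindows, 1, w*w, w*w): broadcasts over heads
    return np.where(diff, _NEG_INF, 0.0)[:, None, :, :].astype(np.float32)


class SwinBlock(Module):
    """One window-attention transformer block, optionally shifted."""

    def __init__(self, dim: int, heads: int, window: int, shift: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.window, self.shift = window, shift
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.rel_bias = RelPosBias2D(window, heads)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, 4 * dim, rng)
        self.drop = Dropout(dropout)
        self._mask_cache: Dict[Tuple[int, int], np.ndarray] = {}

    def _mask(self, H: int, W: int) -> Optional[np.ndarray]:
        if self.shift == 0:
            return None
        key = (H, W)
        if key not in self._mask_cache:
            self._mask_cache[key] = shifted_window_mask(
                H, W, self.window, self.shift)
        return self._mask_cache[key]

    def __call__(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        B, H, W, C = x.shape
        h = self.norm1(x)
        if self.shift:
            h = h.roll((-self.shift, -self.shift), axis=(1, 2))
        wins = window_partition(h, self.window)  # (B*nW, w*w, C)
        mask = self._mask(H, W)
        bias = self.rel_bias()
        if mask is not None:
            nW = mask.shape[0]
            wins = wins.reshape(B, nW, self.window ** 2, C)
            attn_out = self.attn(wins, mask=mask[None], bias=bias)
            attn_out = attn_out.reshape(B * nW, self.window ** 2, C)
        else:
            attn_out = self.attn(wins, bias=bias)
        h = window_reverse(attn_out, self.window, B, H, W)
        if self.shift:
            h = h.roll((self.shift, self.shift), axis=(1, 2))
        x = x + self.drop(h, train, rng)
        return x + self.drop(self.mlp(self.norm2(x)), train, rng)


class PatchEmbed(Module):
    """Non-overlapping 2x2 patch embedding: (B, H, W, C) -> (B, H/2, W/2, D)."""

    def __init__(self, in_ch: int, dim: int, rng: np.random.Generator):
        self.proj = Linear(in_ch * 4, dim, rng)
        self.norm = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        x = x.reshape(B, H // 2, 2, W // 2, 2, C)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // 2, W // 2, 4 * C)
        return self.norm(self.proj(x))


class PatchMerging(Module):
    """2x2 patch merging: halves the grid, doubles the channels."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * dim)
        self.proj = Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        x = x.reshape(B, H // 2, 2, W // 2, 2, C)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // 2, W // 2, 4 * C)
        return self.proj(self.norm(x))


class PixelShuffleUp(Module):
    """Transposed-convolution upsampling (kernel 2, stride 2) as
    a linear map to 4x channels followed by depth-to-space."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.proj = Linear(in_ch, 4 * out_ch, rng)
        self.out_ch = out_ch

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, _ = x.shape
        y = self.proj(x).reshape(B, H, W, 2, 2, self.out_ch)
        y = y.transpose(0, 1, 3, 2, 4, 5)
        return y.reshape(B, 2 * H, 2 * W, self.out_ch)
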