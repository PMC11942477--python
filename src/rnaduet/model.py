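"""Sequence encoder, vision encoder, multimodal fusion, and task heads.

The two encoders produce a text embedding ``Tl`` (one token per k-mer
plus CLS/SEP) and a vision embedding ``Vl`` (L/16 tokens distilled from
the 24 x L x L structural feature stack by a hierarchical windowed-
attention encoder). Fusion blocks exchange information between the two
modalities through paired self- and cross-attention; downstream heads
perform sequence-level classification and base-pair-matrix prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .nn import (Embedding, LayerNorm, Linear, Module, MultiHeadAttention,
                 PatchEmbed, PatchMerging, PixelShuffleUp, SwinBlock, Tensor,
                 TransformerLayer, as_tensor, concatenate)

N_FEATURE_CHANNELS = 24


@dataclass
class ModelConfig:
    """Hyperparameters shared by all model components.

    Defaults are the full-scale configuration (embedding width 768,
    12 sequence-encoder layers, vision stage depths 2/2/6/2, window 7,
    2 fusion blocks); :meth:`toy` gives a width-64 configuration that
    trains in seconds on a CPU.
    """

    L: int = 112
    k: int = 3
    d_model: int = 768
    n_heads: int = 12
    depths: Tuple[int, ...] = (2, 2, 6, 2)
    window: int = 7
    fusion_layers: int = 2
    dropout: float = 0.1
    seq_layers: int = 12

    def __post_init__(self):
        if self.L % 16:
            raise ValueError(f"L={self.L} must be divisible by 16")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_model % 8:
            raise ValueError("d_model must be divisible by 8 (4 vision stages)")

    @classmethod
    def toy(cls, L: int = 112, **overrides) -> "ModelConfig":
        base = dict(L=L, d_model=64, n_heads=8, depths=(2, 2, 2, 2),
                    seq_layers=2, fusion_layers=2)
        base.update(overrides)
        return cls(**base)

    @property
    def dk(self) -> int:
        return self.d_model // self.n_heads

    @property
    def text_len(self) -> int:
        """Lt = L - k + 3 (k-mers plus CLS and SEP)."""
        return self.L - self.k + 3

    @property
    def vision_len(self) -> int:
        """Lv = L / 16."""
        return self.L // 16

    @property
    def pooled_positions(self) -> int:
        """C = Lt + Lv; equals L + L/16 for k = 3."""
        return self.text_len + self.vision_len

    def stage_dim(self, s: int) -> int:
        return (self.d_model // 8) * (1 << s)

    def stage_heads(self, s: int) -> int:
        h = max(1, self.n_heads >> (3 - s))
        while self.stage_dim(s) % h:
            h -= 1
        return h


def _stage_window(grid: int, preferred: int) -> int:
    for w in range(min(preferred, grid), 0, -1):
        if grid % w == 0:
            return w
    return 1


class VisionEncoder(Module):
    """Hierarchical windowed-attention encoder over the feature stack.

    A 2x2 patch embedding halves the grid; three patch mergings halve it
    again (L -> L/16 overall) while doubling channels up to ``d_model``.
    Each stage alternates window attention and shifted-window attention.
    The final (L/16, L/16) grid is mean-pooled along the row axis to give
    L/16 vision tokens.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 pooled: bool = True):
        self.cfg = cfg
        c0 = cfg.stage_dim(0)
        self.patch_embed = PatchEmbed(N_FEATURE_CHANNELS, c0, rng)
        self.stages: List[List[SwinBlock]] = []
        self.merges: List[PatchMerging] = []
        grid = cfg.L // 2
        for s, depth in enumerate(cfg.depths):
            dim = cfg.stage_dim(s)
            w = _stage_window(grid, cfg.window)
            blocks = []
            for b in range(depth):
                # shifting is meaningful only when windows tile a larger grid
                shift = (w // 2) if (b % 2 == 1 and 1 < w < grid) else 0
                blocks.append(SwinBlock(dim, cfg.stage_heads(s), w, shift,
                                        rng, dropout=cfg.dropout))
            self.stages.append(blocks)
            if s < len(cfg.depths) - 1:
                self.merges.append(PatchMerging(dim, rng))
                grid //= 2
        # the pooling norm only exists when the encoder is used as Vl producer
        self.norm = LayerNorm(cfg.d_model) if pooled else None

    def forward_features(self, feats: np.ndarray, train: bool = False,
                         rng=None) -> List[Tensor]:
        """Per-stage feature grids [(B, L/2, L/2, C0), ..., (B, L/16, L/16, D)]."""
        if feats.ndim != 4 or feats.shape[1] != N_FEATURE_CHANNELS:
            raise ValueError(f"expected (B, 24, L, L) input, got {feats.shape}")
        if feats.shape[-1] % 16:
            raise ValueError("spatial size must be divisible by 16")
        x = as_tensor(np.ascontiguousarray(
            feats.transpose(0, 2, 3, 1).astype(np.float32)))
        x = self.patch_embed(x)
        out = []
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x, train=train, rng=rng)
            out.append(x)
            if s < len(self.stages) - 1:
                x = self.merges[s](x)
        return out

    def __call__(self, feats: np.ndarray, train: bool = False, rng=None) -> Tensor:
        """Vision embedding Vl: (B, L/16, d_model)."""
        if self.norm is None:
            raise ValueError("encoder built with pooled=False has no Vl head")
        grid = self.forward_features(feats, train=train, rng=rng)[-1]
        return self.norm(grid.mean(axis=1))  # pool rows -> (B, L/16, D)


class SequenceEncoder(Module):
    """Token + position embedding followed by pre-LN transformer layers."""

    def __init__(self, cfg: ModelConfig, vocab_size: int, pad_id: int,
                 rng: np.random.Generator, max_len: Optional[int] = None):
        self.cfg = cfg
        self.pad_id = pad_id
        self.tok = Embedding(vocab_size, cfg.d_model, rng)
        self.pos = Embedding(max_len or (cfg.L + 3), cfg.d_model, rng)
        self.layers = [TransformerLayer(cfg.d_model, cfg.n_heads, rng,
                                        dropout=cfg.dropout)
                       for _ in range(cfg.seq_layers)]
        self.norm = LayerNorm(cfg.d_model)
        self.vocab_size = vocab_size

    def __call__(self, ids: np.ndarray, train: bool = False, rng=None) -> Tensor:
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None]
        if ids.min() < 0 or ids.max() >= self.vocab_size:
            raise ValueError("token id outside vocabulary")
        B, T = ids.shape
        x = self.tok(ids) + self.pos(np.broadcast_to(np.arange(T), (B, T)))
        mask = None
        if (ids == self.pad_id).any():
            key_pad = (ids == self.pad_id)[:, None, None, :]
            mask = np.where(key_pad, -1e9, 0.0).astype(np.float32)
        for layer in self.layers:
            x = layer(x, mask=mask, train=train, rng=rng)
        return self.norm(x)


def attend(q_src, kv_src, cfg: ModelConfig,
           module: Optional[MultiHeadAttention] = None,
           rng: Optional[np.random.Generator] = None) -> Tensor:
    """Multi-head scaled dot-product attention of ``q_src`` over ``kv_src``.

    With ``q_src is kv_src`` this is self-attention, otherwise
    cross-attention. A fresh parameter set is drawn from ``rng`` unless an
    existing module is supplied.
    """
    q_src, kv_src = as_tensor(q_src), as_tensor(kv_src)
    if q_src.shape[-1] != kv_src.shape[-1]:
        raise ValueError("feature dimension mismatch between Q and KV sources")
    if module is None:
        module = MultiHeadAttention(cfg.d_model, cfg.n_heads,
                                    rng or np.random.default_rng(0))
    return module(q_src, kv_src)


class FusionBlock(Module):
    """Paired self-/cross-attention exchange between text and vision.

    Per modality: concatenate SA(X) and CA(X -> other) along the feature
    axis, project 2D -> D, layer-normalize, and apply SeLU. Shapes are
    preserved so blocks stack.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, h = cfg.d_model, cfg.n_heads
        self.sa_t = MultiHeadAttention(d, h, rng)
        self.ca_t = MultiHeadAttention(d, h, rng)
        self.sa_v = MultiHeadAttention(d, h, rng)
        self.ca_v = MultiHeadAttention(d, h, rng)
        self.lin_t = Linear(2 * d, d, rng)
        self.lin_v = Linear(2 * d, d, rng)
        self.norm_t = LayerNorm(d)
        self.norm_v = LayerNorm(d)

    def __call__(self, tl: Tensor, vl: Tensor,
                 t_key_mask: Optional[np.ndarray] = None
                 ) -> Tuple[Tensor, Tensor]:
        t = concatenate([self.sa_t(tl, mask=t_key_mask),
                         self.ca_t(tl, vl)], axis=-1)
        v = concatenate([self.sa_v(vl),
                         self.ca_v(vl, tl, mask=t_key_mask)], axis=-1)
        t = self.norm_t(self.lin_t(t)).selu()
        v = self.norm_v(self.lin_v(v)).selu()
        return t, v


class MultimodalClassifier(Module):
    """Sequence + vision encoders, fusion stack, mean-pool classifier."""

    def __init__(self, cfg: ModelConfig, vocab_size: int, pad_id: int,
                 n_classes: int, rng: np.random.Generator):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.cfg = cfg
        self.seq = SequenceEncoder(cfg, vocab_size, pad_id, rng)
        self.vis = VisionEncoder(cfg, rng)
        self.fusion = [FusionBlock(cfg, rng) for _ in range(cfg.fusion_layers)]
        self.head = Linear(cfg.d_model, n_classes, rng)
        self.n_classes = n_classes

    def __call__(self, ids: np.ndarray, feats: np.ndarray,
                 train: bool = False, rng=None) -> Tensor:
        tl = self.seq(ids, train=train, rng=rng)
        vl = self.vis(feats, train=train, rng=rng)
        key_pad = (np.asarray(ids) == self.seq.pad_id)
        t_mask = (np.where(key_pad[:, None, None, :], -1e9, 0.0)
                  .astype(np.float32) if key_pad.any() else None)
        for block in self.fusion:
            tl, vl = block(tl, vl, t_key_mask=t_mask)
        pooled = concatenate([tl, vl], axis=1).mean(axis=1)  # (B, D)
        return self.head(pooled).softmax(axis=-1)


class StructurePredictor(Module):
    """U-Net-style base-pair-matrix head over the vision stages.

    The vision stages act as the encoder; at the bottleneck the (L/16)^2
    grid tokens cross-attend to the text embedding (a pure feature
    transformation, no resampling). The decoder then upsamples stage by
    stage with transposed convolutions (pixel-shuffle form), adding the
    matching encoder grid as a skip connection, and ends in a 1-channel
    sigmoid map symmetrized as (P + P^T) / 2.
    """

    def __init__(self, cfg: ModelConfig, vocab_size: int, pad_id: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.seq = SequenceEncoder(cfg, vocab_size, pad_id, rng)
        self.vis = VisionEncoder(cfg, rng, pooled=False)
        d = cfg.d_model
        c0 = cfg.stage_dim(0)
        self.bottleneck = MultiHeadAttention(d, cfg.n_heads, rng)
        self.bottleneck_norm = LayerNorm(d)
        self.up3 = PixelShuffleUp(d, cfg.stage_dim(2), rng)
        self.up2 = PixelShuffleUp(cfg.stage_dim(2), cfg.stage_dim(1), rng)
        self.up1 = PixelShuffleUp(cfg.stage_dim(1), c0, rng)
        self.up0 = PixelShuffleUp(c0, max(2, c0 // 2), rng)
        self.out = Linear(max(2, c0 // 2), 1, rng)

    def __call__(self, ids: np.ndarray, feats: np.ndarray,
                 train: bool = False, rng=None,
                 use_skips: bool = True) -> Tensor:
        tl = self.seq(ids, train=train, rng=rng)
        x1, x2, x3, x4 = self.vis.forward_features(feats, train=train, rng=rng)
        B, g, _, d = x4.shape
        tokens = x4.reshape(B, g * g, d)
        y = self.bottleneck_norm(tokens + self.bottleneck(tokens, tl))
        y = y.reshape(B, g, g, d)
        y = self.up3(y)
        if use_skips:
            y = y + x3
        y = self.up2(y)
        if use_skips:
            y = y + x2
        y = self.up1(y)
        if use_skips:
            y = y + x1
        y = self.up0(y)
        p = self.out(y).sigmoid()          # (B, L, L, 1)
        p = p.reshape(B, self.cfg.L, self.cfg.L)
        return (p + p.swapaxes(-1, -2)) * 0.5


# ---------------------------------------------------------------------
# losses and diagnostics
# ---------------------------------------------------------------------

_EPS = 1e-7


def bce_loss(pred, target) -> Tensor:
    """Mean binary cross-entropy of predicted probabilities."""
    pred = as_tensor(pred)
    target = np.asarray(target, dtype=np.float32)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    p = pred.clip(_EPS, 1.0 - _EPS)
    t = as_tensor(target)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def multiclass_ce(pred, target_idx, label_smoothing: float = 0.0) -> Tensor:
    """Mean negative log-likelihood of class probabilities.

    With ``label_smoothing`` > 0 the target distribution mixes the one-hot
    label with the uniform distribution (standard smoothing).
    """
    pred = as_tensor(pred)
    target_idx = np.asarray(target_idx, dtype=np.int64)
    if pred.ndim != 2 or target_idx.ndim != 1 or pred.shape[0] != len(target_idx):
        raise ValueError("expected (B, K) probabilities and (B,) class indices")
    B, K = pred.shape
    logp = pred.clip(_EPS, 1.0).log()
    if label_smoothing == 0.0:
        return -(logp[np.arange(B), target_idx].mean())
    onehot = np.zeros((B, K), dtype=np.float32)
    onehot[np.arange(B), target_idx] = 1.0
    target = (1.0 - label_smoothing) * onehot + label_smoothing / K
    return -((logp * as_tensor(target)).sum(axis=-1).mean())


def attention_stats(attn: np.ndarray, coords: Optional[np.ndarray] = None,
                    tol: float = 1e-4) -> Tuple[np.ndarray, np.ndarray]:
    """Per-head mean attention distance and mean attention entropy.

    ``attn`` is (heads, Q, K) or (B, heads, Q, K) with rows summing to 1;
    ``coords`` gives token positions (defaults to 0..K-1, and queries are
    assumed aligned with keys when Q == K).
    """
    attn = np.asarray(attn, dtype=np.float64)
    if attn.ndim == 3:
        attn = attn[None]
    B, H, Q, K = attn.shape
    rowsum = attn.sum(axis=-1)
    if np.abs(rowsum - 1.0).max() > tol:
        raise ValueError("attention rows must sum to 1")
    if coords is None:
        coords = np.arange(K, dtype=np.float64)
    qcoords = coords if Q == K else np.arange(Q, dtype=np.float64)
    dist = np.abs(qcoords[:, None] - coords[None, :])
    mean_dist = (attn * dist).sum(axis=-1).mean(axis=(0, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(attn > 0, attn * np.log(attn), 0.0)
    mean_ent = (-plogp.sum(axis=-1)).mean(axis=(0, 2))
    return mean_dist, mean_ent
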