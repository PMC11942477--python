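"""Toy-scale training loops for the classification and structure tasks.

Everything is CPU-sized and seeded: datasets are featurized up front,
splits and shuffles come from one generator, and two runs with the same
inputs and seed produce identical histories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import featurize_records
from .metrics import binary_confusion, metric_report
from .model import (ModelConfig, MultimodalClassifier, StructurePredictor,
                    bce_loss, multiclass_ce)
from .nn import AdamW, tune_allocator
from .synth import LabeledRecord
from .tokenizer import KmerVocab, tokenize_kmers


@dataclass
class TrainResult:
    model: object
    history: List[Dict]
    label_names: List[str]
    val_accuracy: float
    val_scores: Optional[np.ndarray] = None
    val_labels: Optional[np.ndarray] = None


def encode_dataset(records: Sequence[LabeledRecord], cfg: ModelConfig,
                   vocab: KmerVocab, normalize: bool = True
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
    """Featurize + tokenize records at cfg.L; returns (ids, feats, y, labels)."""
    fitted = []
    tok_ids = np.empty((len(records), cfg.text_len), dtype=np.int64)
    for n, rec in enumerate(records):
        seq, _ = rec.seq.pad_or_truncate(cfg.L)
        fitted.append((rec.id, rec.seq))
        tok_ids[n] = vocab.encode(tokenize_kmers(seq, cfg.k), pad_to=cfg.text_len)
    feats, _ = featurize_records(fitted, cfg.L, normalize=normalize)
    label_names = sorted({rec.label for rec in records})
    label_idx = {name: i for i, name in enumerate(label_names)}
    y = np.array([label_idx[rec.label] for rec in records], dtype=np.int64)
    return tok_ids, feats, y, label_names


_NO_DECAY_MARKERS = (".gamma", ".beta", "bias", ".table", ".tok.", ".pos.")


def _make_optimizer(model, lr: float, weight_decay: float) -> AdamW:
    """AdamW with weight decay only on projection/embedding-free weights."""
    named = model.named_parameters()
    params = list(named.values())
    flags = [not any(m in name for m in _NO_DECAY_MARKERS) for name in named]
    return AdamW(params, lr=lr, weight_decay=weight_decay, decay_flags=flags)


def _warmup_cosine(base_lr: float, step: int, total: int,
                   warmup_frac: float = 0.02) -> float:
    warm = max(1.0, warmup_frac * total)
    if step < warm:
        return base_lr * step / warm
    frac = (step - warm) / max(1.0, total - warm)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * frac))


def train_classifier(records: Sequence[LabeledRecord], cfg: ModelConfig,
                     seed: int = 0, epochs: int = 20, batch_size: int = 8,
                     lr: float = 1.2e-3, weight_decay: float = 0.05,
                     val_frac: float = 0.2, schedule: bool = True,
                     label_smoothing: float = 0.1,
                     token_mask_prob: float = 0.1,
                     channel_drop_prob: float = 0.0,
                     shift_augment: bool = True,
                     ema_decay: float = 0.0,
                     early_stop_acc: Optional[float] = None,
                     log_path=None) -> TrainResult:
    """Train the multimodal classifier on labeled records.

    AdamW with a linear-warmup/cosine-decay schedule; a ``val_frac``
    held-out split is evaluated every epoch. Training batches are
    augmented by masking random k-mer tokens to UNK and dropping random
    feature channels (scaled inverted-dropout style) — both discourage
    memorizing individual training sequences. ``val_accuracy`` of the
    result is the best held-out accuracy over the run, and training
    stops early once it reaches ``early_stop_acc`` (if given).
    """
    tune_allocator()
    rng = np.random.default_rng(seed)
    vocab = KmerVocab(cfg.k)
    tok_ids, feats, y, label_names = encode_dataset(records, cfg, vocab)
    n = len(records)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    model = MultimodalClassifier(cfg, len(vocab), vocab.pad_id,
                                 n_classes=len(label_names), rng=rng)
    opt = _make_optimizer(model, lr, weight_decay)
    # evaluation uses an exponential moving average of the weights, which
    # smooths the noisy late-training optima of small-batch runs
    params = model.parameters()
    ema = [p.data.copy() for p in params] if ema_decay > 0 else None
    n_steps = epochs * math.ceil(len(tr_idx) / batch_size)
    step = 0
    history: List[Dict] = []
    best_acc = 0.0
    val_probs = None
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(order), batch_size):
            if schedule:
                opt.lr = _warmup_cosine(lr, step, n_steps)
            sel = tr_idx[order[start : start + batch_size]]
            batch_ids = tok_ids[sel]
            batch_feats = feats[sel]
            if shift_augment:
                # circular translation: the planted-signal tasks are
                # translation-invariant, so roll k-mer tokens (between the
                # CLS/SEP specials) and the feature grid by one offset
                batch_ids = batch_ids.copy()
                batch_feats = batch_feats.copy()
                for b in range(len(sel)):
                    shift = int(rng.integers(0, cfg.L))
                    inner = batch_ids[b, 1:-1]
                    batch_ids[b, 1:-1] = np.roll(inner, shift)
                    batch_feats[b] = np.roll(batch_feats[b], (shift, shift),
                                             axis=(1, 2))
            if token_mask_prob > 0:
                if not shift_augment:
                    batch_ids = batch_ids.copy()
                maskable = batch_ids >= 4  # specials occupy ids 0-3
                hit = (rng.random(batch_ids.shape) < token_mask_prob) & maskable
                batch_ids[hit] = vocab.unk_id
            if channel_drop_prob > 0:
                keep = (rng.random((len(sel), feats.shape[1], 1, 1))
                        >= channel_drop_prob)
                batch_feats = (batch_feats * keep
                               / (1.0 - channel_drop_prob)).astype(np.float32)
            probs = model(batch_ids, batch_feats, train=True, rng=rng)
            loss = multiclass_ce(probs, y[sel],
                                 label_smoothing=label_smoothing)
            model.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                for e, p in zip(ema, params):
                    e *= ema_decay
                    e += (1.0 - ema_decay) * p.data
            step += 1
            losses.append(float(loss.data))
        if ema is not None:
            raw = [p.data for p in params]
            for p, e in zip(params, ema):
                p.data = e
        val_probs = predict_classifier(model, tok_ids[val_idx],
                                       feats[val_idx], batch_size=32)
        if ema is not None:
            for p, r in zip(params, raw):
                p.data = r
        val_pred = val_probs.argmax(axis=1)
        val_acc = float((val_pred == y[val_idx]).mean())
        best_acc = max(best_acc, val_acc)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_accuracy": val_acc})
        if early_stop_acc is not None and val_acc >= early_stop_acc:
            break
    if log_path is not None:
        with open(log_path, "w") as f:
            for row in history:
                f.write(json.dumps(row) + "\n")
    scores = val_probs[:, 1] if val_probs.shape[1] == 2 else None
    return TrainResult(model, history, label_names, best_acc,
                       val_scores=scores, val_labels=y[val_idx])


def predict_classifier(model: MultimodalClassifier, tok_ids: np.ndarray,
                       feats: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Deterministic (dropout-off) class probabilities."""
    out = []
    for start in range(0, len(tok_ids), batch_size):
        probs = model(tok_ids[start : start + batch_size],
                      feats[start : start + batch_size], train=False)
        out.append(probs.data)
    return np.concatenate(out, axis=0)


def train_structure(records: Sequence[LabeledRecord], cfg: ModelConfig,
                    seed: int = 0, epochs: int = 5, batch_size: int = 8,
                    lr: float = 3e-5, weight_decay: float = 0.05,
                    val_frac: float = 0.2, log_path=None) -> TrainResult:
    """Train the base-pair-matrix head with binary cross-entropy."""
    tune_allocator()
    rng = np.random.default_rng(seed)
    vocab = KmerVocab(cfg.k)
    tok_ids, feats, _, _ = encode_dataset(records, cfg, vocab)
    targets = np.stack([rec.structure.to_matrix() for rec in records])
    n = len(records)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    model = StructurePredictor(cfg, len(vocab), vocab.pad_id, rng=rng)
    opt = _make_optimizer(model, lr, weight_decay)
    history = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(order), batch_size):
            sel = tr_idx[order[start : start + batch_size]]
            pred = model(tok_ids[sel], feats[sel], train=True, rng=rng)
            loss = bce_loss(pred, targets[sel])
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        # held-out pair-level F1 at threshold 0.5
        f1s = []
        for start in range(0, len(val_idx), batch_size):
            sel = val_idx[start : start + batch_size]
            pred = model(tok_ids[sel], feats[sel], train=False).data
            for b in range(len(sel)):
                c = binary_confusion(np.triu(pred[b], 1) > 0.5,
                                     np.triu(targets[sel[b]], 1) > 0.5)
                f1s.append(metric_report(c)["F1"])
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_f1": float(np.mean(f1s))})
    if log_path is not None:
        with open(log_path, "w") as f:
            for row in history:
                f.write(json.dumps(row) + "\n")
    return TrainResult(model, history, ["unpaired", "paired"],
                       history[-1]["val_f1"])
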