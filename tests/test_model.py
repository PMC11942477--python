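"""Architecture contracts: shapes, determinism, fusion, heads, diagnostics."""

import math

import numpy as np
import pytest

from rnaduet.model import (ModelConfig, MultimodalClassifier, SequenceEncoder,
                           StructurePredictor, VisionEncoder, attend,
                           attention_stats, bce_loss, multiclass_ce)
from rnaduet.nn import MultiHeadAttention, Tensor
from rnaduet.synth import SynthSpec, motif_dataset, structure_dataset
from rnaduet.tokenizer import KmerVocab, tokenize_kmers
from rnaduet.train import encode_dataset


@pytest.fixture(scope="module")
def small_setup():
    """Toy config at L=32 with a tiny encoded dataset (shared, read-only)."""
    cfg = ModelConfig.toy(L=32)
    vocab = KmerVocab(3)
    records = motif_dataset(SynthSpec(n_records=6, L=32, seed=0,
                                      motifs=(("pos", "GGCCGG"),
                                              ("neg", "AUAUAU"))))
    ids, feats, y, names = encode_dataset(records, cfg, vocab)
    return cfg, vocab, ids, feats, y


class TestConfig:
    def test_derived_lengths_at_full_scale(self):
        cfg = ModelConfig.toy(L=112)
        assert cfg.text_len == 112
        assert cfg.vision_len == 7
        assert cfg.pooled_positions == 119  # C = L + L/16 for k = 3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(L=100)           # not divisible by 16
        with pytest.raises(ValueError):
            ModelConfig(L=112, d_model=65)


class TestVisionEncoder:
    def test_output_is_l_over_16_tokens(self):
        cfg = ModelConfig.toy(L=112)
        enc = VisionEncoder(cfg, np.random.default_rng(0))
        feats = np.random.default_rng(1).random((1, 24, 112, 112),
                                                dtype=np.float32)
        vl = enc(feats)
        assert vl.shape == (1, 7, 64)

    def test_zero_input_finite_and_deterministic(self, small_setup):
        cfg, *_ = small_setup
        enc = VisionEncoder(cfg, np.random.default_rng(0))
        zeros = np.zeros((2, 24, 32, 32), np.float32)
        a, b = enc(zeros), enc(zeros)
        assert np.isfinite(a.data).all()
        np.testing.assert_array_equal(a.data, b.data)

    def test_rejects_bad_spatial_size(self):
        cfg = ModelConfig.toy(L=32)
        enc = VisionEncoder(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            enc(np.zeros((1, 24, 30, 30), np.float32))


class TestSequenceEncoder:
    def test_shape_and_position_sensitivity(self, small_setup):
        cfg, vocab, ids, *_ = small_setup
        enc = SequenceEncoder(cfg, len(vocab), vocab.pad_id,
                              np.random.default_rng(0))
        out = enc(ids[:1])
        assert out.shape == (1, cfg.text_len, cfg.d_model)
        swapped = ids[:1].copy()
        swapped[0, 3], swapped[0, 7] = swapped[0, 7], swapped[0, 3]
        if not np.array_equal(swapped, ids[:1]):
            assert not np.allclose(enc(swapped).data, out.data)

    def test_out_of_vocab_id_rejected(self, small_setup):
        cfg, vocab, ids, *_ = small_setup
        enc = SequenceEncoder(cfg, len(vocab), vocab.pad_id,
                              np.random.default_rng(0))
        bad = ids[:1].copy()
        bad[0, 0] = len(vocab) + 5
        with pytest.raises(ValueError):
            enc(bad)


class TestAttention:
    def test_single_key_returns_projected_value(self):
        rng = np.random.default_rng(0)
        mha = MultiHeadAttention(16, 4, rng)
        q = Tensor(rng.normal(size=(1, 5, 16)).astype(np.float32))
        kv = Tensor(rng.normal(size=(1, 1, 16)).astype(np.float32))
        out = mha(q, kv).data
        # with one key every query attends to the same value row
        for row in range(5):
            np.testing.assert_allclose(out[0, row], out[0, 0], atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        mha = MultiHeadAttention(16, 4, rng)
        x = Tensor(rng.normal(size=(2, 6, 16)).astype(np.float32))
        mha(x)
        np.testing.assert_allclose(mha._last_attn.sum(axis=-1), 1.0,
                                   atol=1e-6)

    def test_dim_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        cfg = ModelConfig.toy(L=32)
        with pytest.raises(ValueError):
            attend(np.zeros((1, 3, 64), np.float32),
                   np.zeros((1, 3, 32), np.float32), cfg)


class TestFusionAndClassifier:
    def test_fusion_preserves_shapes(self, small_setup):
        from rnaduet.model import FusionBlock
        cfg, *_ = small_setup
        rng = np.random.default_rng(0)
        block = FusionBlock(cfg, rng)
        tl = Tensor(rng.normal(size=(2, cfg.text_len, 64)).astype(np.float32))
        vl = Tensor(rng.normal(size=(2, cfg.vision_len, 64)).astype(np.float32))
        t2, v2 = block(tl, vl)
        assert t2.shape == tl.shape and v2.shape == vl.shape

    def test_probabilities_sum_to_one(self, small_setup):
        cfg, vocab, ids, feats, y = small_setup
        model = MultimodalClassifier(cfg, len(vocab), vocab.pad_id, 3,
                                     np.random.default_rng(0))
        probs = model(ids[:4], feats[:4])
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_forward_deterministic_with_dropout_off(self, small_setup):
        cfg, vocab, ids, feats, y = small_setup
        model = MultimodalClassifier(cfg, len(vocab), vocab.pad_id, 2,
                                     np.random.default_rng(0))
        a = model(ids[:2], feats[:2], train=False).data
        b = model(ids[:2], feats[:2], train=False).data
        np.testing.assert_array_equal(a, b)

    def test_n_classes_below_two_rejected(self, small_setup):
        cfg, vocab, *_ = small_setup
        with pytest.raises(ValueError):
            MultimodalClassifier(cfg, len(vocab), vocab.pad_id, 1,
                                 np.random.default_rng(0))

    def test_gradient_reaches_every_parameter(self, small_setup):
        cfg, vocab, ids, feats, y = small_setup
        model = MultimodalClassifier(cfg, len(vocab), vocab.pad_id, 2,
                                     np.random.default_rng(0))
        probs = model(ids[:4], feats[:4])
        loss = multiclass_ce(probs, y[:4])
        model.zero_grad()
        loss.backward()
        for name, p in model.named_parameters().items():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.abs(p.grad).max() > 0, f"zero gradient for {name}"


class TestStructureHead:
    @pytest.fixture(scope="class")
    def rss_setup(self):
        cfg = ModelConfig.toy(L=32)
        vocab = KmerVocab(3)
        records = structure_dataset(3, 32, seed=1)
        ids, feats, _, _ = encode_dataset(records, cfg, vocab)
        model = StructurePredictor(cfg, len(vocab), vocab.pad_id,
                                   np.random.default_rng(0))
        return cfg, model, ids, feats, records

    def test_output_symmetric_probability_matrix(self, rss_setup):
        cfg, model, ids, feats, _ = rss_setup
        out = model(ids[:2], feats[:2]).data
        assert out.shape == (2, 32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0
        np.testing.assert_allclose(out, np.swapaxes(out, -1, -2), atol=1e-6)

    def test_skip_connections_are_live(self, rss_setup):
        cfg, model, ids, feats, _ = rss_setup
        with_skips = model(ids[:1], feats[:1], use_skips=True).data
        without = model(ids[:1], feats[:1], use_skips=False).data
        assert not np.allclose(with_skips, without)

    def test_gradient_flows_through_unet(self, rss_setup):
        cfg, model, ids, feats, records = rss_setup
        target = np.stack([r.structure.to_matrix() for r in records[:2]])
        loss = bce_loss(model(ids[:2], feats[:2]), target)
        model.zero_grad()
        loss.backward()
        for name, p in model.named_parameters().items():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name


class TestLosses:
    def test_bce_closed_forms(self):
        assert float(bce_loss(np.array([0.5]), np.array([1.0])).data) == \
            pytest.approx(math.log(2), rel=1e-6)
        near_zero = float(bce_loss(np.array([1.0]), np.array([1.0])).data)
        assert 0 <= near_zero < 1e-5

    def test_multiclass_uniform(self):
        probs = np.full((2, 13), 1 / 13)
        assert float(multiclass_ce(probs, np.array([0, 5])).data) == \
            pytest.approx(math.log(13), rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestAttentionStats:
    def test_delta_attention(self):
        attn = np.eye(5)[None]  # one head, each query attends to itself
        dist, ent = attention_stats(attn)
        assert dist[0] == 0.0 and ent[0] == 0.0

    def test_uniform_attention(self):
        n = 8
        attn = np.full((1, n, n), 1 / n)
        dist, ent = attention_stats(attn)
        assert ent[0] == pytest.approx(math.log(n))
        expected = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        expected = (expected / n).sum(axis=1).mean()
        assert dist[0] == pytest.approx(expected)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            attention_stats(np.full((1, 4, 4), 0.3))
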