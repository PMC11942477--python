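"""Structural feature stack: examples, oracles, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnaduet.features import (BPS_LABELS, REGISTRY, bms_maps, bps_tensor,
                              bps_tensor_full, build_feature_stack,
                              featurize_records, load_hdf5, lpss_matrix,
                              manhattan_distance, rcm_matrix, save_hdf5,
                              spatial_distance, srs_maps)
from rnaduet.sequence import PairRules, RnaSequence

from _oracles import (bms_count_oracle, max_matching_oracle, random_sequence,
                      srs_count_oracle)

H3 = PairRules(min_loop=3)
H0 = PairRules(min_loop=0)

seq_strategy = st.text(alphabet="ACGU", min_size=1, max_size=12)


class TestLpss:
    @pytest.mark.parametrize("bases,rules,entry,expected", [
        ("AAAA", H3, None, 0),          # A-A is never admissible
        ("GAAAC", H3, (0, 4), 1),
        ("GGGAAACCC", H3, (0, 8), 3),
    ])
    def test_examples(self, bases, rules, entry, expected):
        m = lpss_matrix(RnaSequence(bases), rules)
        if entry is None:
            assert m.max() == expected
        else:
            assert m[entry] == expected

    def test_subfragments_of_single_hairpin_are_zero(self):
        m = lpss_matrix(RnaSequence("GAAAC"), H3)
        assert m[0, 4] == 1
        inner = m.copy()
        inner[0, 4] = inner[4, 0] = 0
        assert inner.max() == 0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seq_strategy, st.integers(0, 4))
    def test_matches_recursive_oracle(self, bases, h):
        seq = RnaSequence(bases)
        rules = PairRules(min_loop=h)
        m = lpss_matrix(seq, rules)
        L = len(seq)
        assert m[0, L - 1] == max_matching_oracle(seq, rules, 0, L - 1)
        if L >= 3:
            assert m[1, L - 1] == max_matching_oracle(seq, rules, 1, L - 1)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seq_strategy)
    def test_monotone_and_bounded(self, bases):
        seq = RnaSequence(bases)
        m = lpss_matrix(seq, H3)
        L = len(seq)
        for i in range(L):
            for j in range(i, L):
                assert m[i, j] <= (j - i + 1) // 2
                if i > 0:
                    assert m[i, j] <= m[i - 1, j]
                if j < L - 1:
                    assert m[i, j] <= m[i, j + 1]

    def test_symmetric_zero_diagonal(self):
        m = lpss_matrix(RnaSequence("GGGAAACCCAU"), H3)
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)


class TestSrsBms:
    def test_srs_example(self):
        s = srs_maps(RnaSequence("AUU"), H0)
        assert s[0, 0, 2] == 1   # the A sees partners at both U positions
        assert s[1, 0, 2] == 0   # each U has only one partner (the A)

    def test_srs_loop_constraint_excludes_everything(self):
        assert srs_maps(RnaSequence("ACGU"), H3).max() == 0

    def test_bms_example(self):
        b = bms_maps(RnaSequence("AAU"), H0)
        assert b[0, 0, 2] == 2 and b[1, 0, 2] == 1 and b[4, 0, 2] == 3

    def test_bms_ignores_non_au_rules(self):
        assert bms_maps(RnaSequence("GGCC"), H0).max() == 0

    def test_bms_loop_constraint(self):
        assert bms_maps(RnaSequence("AU"), PairRules(min_loop=1)).max() == 0

    @pytest.mark.parametrize("fn", [srs_maps, bms_maps])
    def test_aggregate_channel_is_sum(self, fn):
        seq = RnaSequence("GGAUCCGAUAUGC")
        maps = fn(seq, H0)
        np.testing.assert_array_equal(maps[4], maps[:4].sum(axis=0))

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 12), st.integers(0, 3))
    def test_matches_direct_count_oracle(self, seed, L, h):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, L)
        rules = PairRules(min_loop=h)
        srs = srs_maps(seq, rules)
        bms = bms_maps(seq, rules)
        for ch, base in enumerate("AUCG"):
            for i in range(L):
                for j in range(i + 1, L):
                    assert srs[ch, i, j] == srs_count_oracle(seq, rules, base, i, j)
                    assert bms[ch, i, j] == bms_count_oracle(seq, rules, base, i, j)


class TestRcm:
    def test_inadmissible_pair_scores_zero(self):
        m = rcm_matrix(RnaSequence("AA"), H0)
        assert m[0, 1] == 0

    def test_single_pair_no_extension(self):
        assert rcm_matrix(RnaSequence("GC"), H0)[0, 1] == pytest.approx(3.0)

    def test_outward_extension(self):
        m = rcm_matrix(RnaSequence("GGCC"), H0)
        assert m[1, 2] == pytest.approx(3.0 + math.exp(-0.5) * 3.0, rel=1e-6)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            rcm_matrix(RnaSequence("GC"), H0, sigma=0.0)

    def test_symmetric_nonnegative(self):
        m = rcm_matrix(RnaSequence("GGGAAACCCAUGCA"), H3)
        assert np.allclose(m, m.T) and m.min() >= 0


class TestDistances:
    def test_spatial_examples(self):
        assert spatial_distance(RnaSequence("AA"))[0, 1] == pytest.approx(1.0)
        assert spatial_distance(RnaSequence("AC"))[0, 1] == pytest.approx(
            math.sqrt(3.0), rel=1e-6)

    def test_spatial_diagonal_zero_symmetric(self):
        m = spatial_distance(RnaSequence("ACGUACGU"))
        assert np.all(np.diag(m) == 0) and np.allclose(m, m.T)

    def test_manhattan_values(self):
        m = manhattan_distance(RnaSequence("AACN"))
        assert m[0, 1] == 0      # same base
        assert m[0, 2] == 2      # different bases
        assert m[0, 3] == 1      # base vs N (zero one-hot)


class TestBps:
    def test_ordered_channel_entries(self):
        t = bps_tensor(RnaSequence("AU"))
        assert t[BPS_LABELS.index("AU"), 0, 1] == 1
        assert t[BPS_LABELS.index("UU"), 0, 1] == 0
        assert t[BPS_LABELS.index("UU"), 1, 1] == 1

    def test_sixteen_channels_partition_unity(self):
        full, labels = bps_tensor_full(RnaSequence("ACGUGGCAU"))
        assert full.shape[0] == 16
        np.testing.assert_array_equal(full.sum(axis=0), np.ones((9, 9)))

    def test_deleted_channels_are_transposes_of_kept(self):
        seq = RnaSequence("ACGUGGCAUCC")
        full, labels = bps_tensor_full(seq)
        kept = bps_tensor(seq)
        deleted = [l for l in labels if l not in BPS_LABELS]
        assert len(deleted) == 6
        for label in deleted:
            rev = label[::-1]
            np.testing.assert_array_equal(
                full[labels.index(label)], kept[BPS_LABELS.index(rev)].T)

    def test_kept_plus_transposes_partition_unity(self):
        seq = RnaSequence("GAUCGGAC")
        kept = bps_tensor(seq)
        total = kept.sum(axis=0)
        for c, label in enumerate(BPS_LABELS):
            if label[0] != label[1]:
                total = total + kept[c].T
        np.testing.assert_array_equal(total, np.ones((8, 8)))


class TestStack:
    def test_channel_count_and_registry(self):
        fs = build_feature_stack(RnaSequence("GGGAAACCCAUGCAAU"), H3)
        assert fs.data.shape[0] == 24 == len(REGISTRY)
        assert fs.registry == REGISTRY

    def test_single_base_degenerate_channels(self):
        fs = build_feature_stack(RnaSequence("AAAA"), H3, normalize=False)
        for name in ("LPSS", "RCM", "SRS_ALL", "BMS_ALL", "MANHATTAN"):
            assert fs.channel(name).max() == 0
        assert fs.channel("BPS_AA").min() == 1

    def test_normalization_bounds(self):
        fs = build_feature_stack(RnaSequence("GGGAAACCCAUGCAAU"), H3,
                                 normalize=True)
        for c in range(14):
            mx = fs.data[c].max()
            assert mx == pytest.approx(1.0) or mx == 0.0

    def test_symmetry_of_non_bps_channels(self):
        fs = build_feature_stack(RnaSequence("GGAUACGUAGCCAUGG"), H3,
                                 normalize=False)
        for c in range(14):
            np.testing.assert_allclose(fs.data[c], fs.data[c].T, atol=1e-6)

    def test_deterministic(self):
        a = build_feature_stack(RnaSequence("GGAUACGUAGCC"), H3)
        b = build_feature_stack(RnaSequence("GGAUACGUAGCC"), H3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_padding_rows_zeroed_and_finite(self):
        feats, ids = featurize_records(
            [("short", RnaSequence("GGGAAACCC"))], L=16)
        assert np.isfinite(feats).all()
        assert feats[0, :, 9:, :].max() == 0
        assert feats[0, :, :, 9:].max() == 0

    def test_hdf5_roundtrip(self, tmp_path):
        feats, ids = featurize_records(
            [("a", RnaSequence("GGGAAACCC")), ("b", RnaSequence("AUAUAUAU"))],
            L=16)
        path = tmp_path / "stack.h5"
        save_hdf5(path, feats, ids, params={"L": 16})
        back, back_ids, registry, params = load_hdf5(path)
        np.testing.assert_array_equal(back, feats)
        assert back_ids == ["a", "b"]
        assert registry == REGISTRY
        assert params == {"L": 16}
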