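"""Corruption transforms and pretraining losses."""

import numpy as np
import pytest

from anatodetect.networks import desk_swin_config, SwinEncoderConfig
from anatodetect.nn import Tensor, no_grad
from anatodetect.ssl import (CorruptionConfig, SSLAutoencoder, coarse_dropout,
                             contrastive_loss, make_view_pair, pixel_shuffle,
                             reconstruction_loss, ssl_total_loss,
                             build_ssl_autoencoder)

PATCH = np.full((1, 16, 16, 16), 0.9, dtype=np.float32)


class TestCoarseDropout:
    def test_zero_regions_identity(self, rng):
        patch = rng.random((2, 10, 10, 10)).astype(np.float32)
        cfg = CorruptionConfig(n_dropout_regions=0)
        assert np.array_equal(coarse_dropout(patch, cfg, 3), patch)

    def test_standard_variant_value_range(self):
        cfg = CorruptionConfig(n_dropout_regions=2, dropout_size_range=(3, 5),
                               invert_probability=0.0)
        out = coarse_dropout(PATCH, cfg, 5)
        changed = out != PATCH
        assert changed.any()
        assert np.all(out[changed] >= 0.0) and np.all(out[changed] <= 0.2)
        assert np.all(out[~changed] == 0.9)

    def test_inverted_variant_retains_exactly_region(self):
        cfg = CorruptionConfig(n_dropout_regions=1, dropout_size_range=(2, 2),
                               invert_probability=1.0)
        out = coarse_dropout(PATCH, cfg, 9)
        assert int((out == 0.9).sum()) == 8  # one 2^3 region survives

    def test_deterministic(self):
        cfg = CorruptionConfig()
        a = coarse_dropout(PATCH, cfg, 11)
        b = coarse_dropout(PATCH, cfg, 11)
        assert np.array_equal(a, b)

    def test_oversized_region_rejected(self):
        cfg = CorruptionConfig(dropout_size_range=(64, 64))
        with pytest.raises(ValueError):
            coarse_dropout(PATCH, cfg, 0)

    def test_value_range_validated(self):
        with pytest.raises(ValueError):
            CorruptionConfig(dropout_value_range=(0.0, 1.5))


class TestPixelShuffle:
    def test_constant_region_unchanged(self):
        cfg = CorruptionConfig(n_shuffle_regions=2, shuffle_size_range=(3, 5))
        assert np.array_equal(pixel_shuffle(PATCH, cfg, 1), PATCH)

    def test_multiset_conservation_whole_patch(self, rng):
        patch = rng.random((2, 8, 8, 8)).astype(np.float32)
        cfg = CorruptionConfig(n_shuffle_regions=1, shuffle_size_range=(8, 8))
        out = pixel_shuffle(patch, cfg, 2)
        for c in range(2):
            assert np.array_equal(np.sort(out[c].ravel()),
                                  np.sort(patch[c].ravel()))
        assert not np.array_equal(out, patch)

    def test_channels_shuffled_independently(self, rng):
        base = rng.random((8, 8, 8)).astype(np.float32)
        patch = np.stack([base, base])  # identical channels
        cfg = CorruptionConfig(n_shuffle_regions=1, shuffle_size_range=(8, 8))
        differs = sum(
            not np.array_equal(pixel_shuffle(patch, cfg, s)[0],
                               pixel_shuffle(patch, cfg, s)[1])
            for s in range(10))
        assert differs == 10  # equal permutations would keep channels equal


class TestMakeViewPair:
    def test_zero_corruption_returns_original(self, rng):
        patch = rng.random((2, 8, 8, 8)).astype(np.float32)
        cfg = CorruptionConfig(n_dropout_regions=0, n_shuffle_regions=0)
        a, b, tgt = make_view_pair(patch, cfg, 4)
        assert np.array_equal(a, patch) and np.array_equal(b, patch)
        assert np.array_equal(tgt, patch)

    def test_views_differ(self, rng):
        patch = rng.random((1, 12, 12, 12)).astype(np.float32)
        cfg = CorruptionConfig(dropout_size_range=(3, 6),
                               shuffle_size_range=(3, 6))
        a, b, _ = make_view_pair(patch, cfg, 4)
        assert not np.array_equal(a, b)

    def test_region_geometry_shared_across_channels(self):
        patch = np.full((3, 12, 12, 12), 0.9, dtype=np.float32)
        cfg = CorruptionConfig(n_dropout_regions=2, dropout_size_range=(3, 4),
                               invert_probability=0.0, n_shuffle_regions=0)
        out = coarse_dropout(patch, cfg, 21)
        masks = [out[c] != 0.9 for c in range(3)]
        assert np.array_equal(masks[0], masks[1])
        assert np.array_equal(masks[0], masks[2])


class TestLosses:
    def test_l1_examples(self):
        assert reconstruction_loss(np.zeros(4), np.zeros(4)) == 0.0
        assert reconstruction_loss(np.ones(8), np.zeros(8)) == 1.0
        assert reconstruction_loss(np.array([0.0, 0.5]),
                                   np.array([1.0, 0.5])) == 0.5

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros(3), np.zeros(4))

    def test_contrastive_identical_features_log3(self):
        f = np.ones((2, 8))
        assert contrastive_loss(f, f, 0.05) == pytest.approx(np.log(3), rel=1e-6)

    def test_contrastive_scale_invariance(self, rng):
        a = rng.normal(size=(3, 16))
        b = rng.normal(size=(3, 16))
        assert contrastive_loss(a, b) == pytest.approx(
            contrastive_loss(10.0 * a, 10.0 * b), rel=1e-6)

    def test_contrastive_brute_force_oracle(self):
        # B = 2, pairwise-orthogonal unit features
        a = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        b = np.array([[0, 0, 1.0, 0], [0, 0, 0, 1.0]])
        tau = 0.05
        z = np.vstack([a, b])
        loss = 0.0
        for i in range(4):
            pos = (i + 2) % 4
            sims = [z[i] @ z[k] / tau for k in range(4) if k != i]
            loss += -np.log(np.exp(z[i] @ z[pos] / tau) /
                            np.sum(np.exp(sims)))
        assert contrastive_loss(a, b, tau) == pytest.approx(loss / 4, rel=1e-6)

    def test_contrastive_needs_negatives(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.ones((1, 4)), np.ones((1, 4)))

    def test_total_loss_algebra(self, rng):
        for _ in range(50):
            l_rec = float(rng.uniform(0, 3))
            l_con = float(rng.uniform(0, 3))
            assert ssl_total_loss(l_rec, l_con) == pytest.approx(
                l_rec * (1 + l_con), rel=1e-12)
        assert ssl_total_loss(0.0, 123.0) == 0.0
        assert ssl_total_loss(1.0, 0.5) == 1.5
        assert ssl_total_loss(0.7, 0.0) == 0.7


class TestAutoencoder:
    def test_reconstruction_shape_and_bottleneck(self):
        model = build_ssl_autoencoder(desk_swin_config(2), seed=0)
        x = Tensor(np.random.default_rng(0).random((1, 2, 32, 32, 32),
                                                   ).astype(np.float32))
        with no_grad():
            recon, feat = model(x)
        assert recon.shape == (1, 2, 32, 32, 32)
        assert feat.shape == (1, desk_swin_config(2).widths[-1])
        with no_grad():
            bottleneck = model.encoder(x).levels[-1]
        assert bottleneck.shape[2:] == (2, 2, 2)  # stride 16

    def test_indivisible_patch_rejected(self):
        model = build_ssl_autoencoder(desk_swin_config(2), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model(Tensor(np.zeros((1, 2, 24, 24, 24), dtype=np.float32)))

    def test_param_count_grows_with_width(self):
        small = build_ssl_autoencoder(desk_swin_config(2), seed=0)
        cfg = desk_swin_config(2)
        big = build_ssl_autoencoder(
            SwinEncoderConfig(cfg.depths, cfg.embed_dim * 2, cfg.window,
                              cfg.heads, cfg.in_channels), seed=0)
        assert big.num_parameters() > small.num_parameters()

    def test_checkpoint_roundtrip_bit_exact(self, tmp_path):
        from anatodetect.checkpoint import load_checkpoint, save_checkpoint
        model = build_ssl_autoencoder(desk_swin_config(2), seed=1)
        x = Tensor(np.random.default_rng(3).random((1, 2, 32, 32, 32),
                                                   ).astype(np.float32))
        with no_grad():
            ref, _ = model(x)
        save_checkpoint(tmp_path / "ck", model, {"kind": "ssl"})
        clone = build_ssl_autoencoder(desk_swin_config(2), seed=99)
        load_checkpoint(tmp_path / "ck", clone)
        with no_grad():
            out, _ = clone(x)
        assert np.array_equal(ref.data, out.data)
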