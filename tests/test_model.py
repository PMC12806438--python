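"""Architecture contracts: positions, shared encoder, heads, persistence."""

import numpy as np
import pytest

from delayformer.model import Delayformer, ModelConfig, sinusoidal_positions

from conftest import tiny_model_config


class TestSinusoidalPositions:
    def test_row_zero(self):
        pe = sinusoidal_positions(4, 8)
        assert np.array_equal(pe[0, 0::2], np.zeros(4))
        assert np.array_equal(pe[0, 1::2], np.ones(4))

    def test_closed_form_entries(self):
        pe = sinusoidal_positions(3, 6)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))
        assert pe[1, 1] == pytest.approx(np.cos(1.0))
        assert pe[2, 2] == pytest.approx(np.sin(2.0 / 10000 ** (2 / 6)))

    def test_deterministic_and_odd_D_rejected(self):
        assert np.array_equal(sinusoidal_positions(5, 10), sinusoidal_positions(5, 10))
        with pytest.raises(ValueError):
            sinusoidal_positions(5, 7)


class TestConfigValidation:
    def test_geometry_checked_eagerly(self):
        with pytest.raises(ValueError):
            tiny_model_config(L=10)  # p2=3 does not divide 10
        with pytest.raises(ValueError):
            tiny_model_config(D=15)  # not divisible by heads
        with pytest.raises(ValueError):
            tiny_model_config(n_layers=0)

    def test_token_count(self):
        cfg = ModelConfig(W=96, H=96, N=30, L=49, p1=6, p2=7, D=128)
        assert cfg.n_tokens == 56 and cfg.token_dim == 42


class TestEmbedding:
    def test_zero_projection_gives_positional_matrix(self, rng):
        m = Delayformer(tiny_model_config(), seed=0)
        m.params["embed.W"][:] = 0
        m.params["embed.b"][:] = 0
        tokens = rng.normal(size=(3, m.config.n_tokens, m.config.token_dim)).astype(np.float32)
        h0 = m.embed_patches(tokens)
        assert np.allclose(h0, np.broadcast_to(m.pe, h0.shape))

    def test_shape_contract_benchmark_geometry(self, rng):
        cfg = ModelConfig(W=96, H=96, N=2, L=49, p1=6, p2=7, D=128, n_layers=1)
        m = Delayformer(cfg, seed=0)
        tokens = m.tokenize(rng.normal(size=(1, 96, 2)))
        assert tokens.shape == (2, 56, 42)
        assert m.embed_patches(tokens).shape == (2, 56, 128)

    def test_identical_windows_share_embedding(self, rng):
        m = Delayformer(tiny_model_config(), seed=0)
        win = rng.normal(size=(1, 32, 6))
        win[:, :, 1] = win[:, :, 0]  # duplicate channel
        tokens = m.tokenize(win)
        h0 = m.embed_patches(tokens)
        assert np.array_equal(h0[0], h0[1])


class TestEncoderBlock:
    def test_shape_preserved(self, rng):
        m = Delayformer(tiny_model_config(), seed=0)
        h = rng.normal(size=(4, 18, 16)).astype(np.float32)
        assert m.encoder_block(h, 0).shape == h.shape

    def test_postnorm_output_rows_standardized_at_init(self, rng):
        # LayerNorm affine is identity at init, so each output row is
        # standardized across the feature axis
        m = Delayformer(tiny_model_config(), seed=0)
        out = m.encoder_block(rng.normal(size=(4, 18, 16)).astype(np.float32), 1)
        assert np.allclose(out.mean(axis=-1), 0, atol=1e-5)
        assert np.allclose(out.var(axis=-1), 1, atol=1e-3)

    def test_token_permutation_equivariance(self, rng):
        # attention + pointwise ops commute with permuting the token axis
        m = Delayformer(tiny_model_config(), seed=0)
        h = rng.normal(size=(2, 18, 16)).astype(np.float32)
        perm = rng.permutation(18)
        out = m.encoder_block(h, 0)
        out_perm = m.encoder_block(h[:, perm, :], 0)
        assert np.allclose(out_perm, out[:, perm, :], atol=1e-5)

    def test_hand_coded_single_head_reference(self, rng):
        """Post-norm block equals an independent loop-based reference on a 4-token toy."""
        cfg = tiny_model_config(D=6, n_heads=1, ff_dim=5, dtype="float64")
        m = Delayformer(cfg, seed=7)
        h = rng.normal(size=(1, 4, 6))
        P = m.params

        def ln(v, g, b, eps=1e-5):
            mu, var = v.mean(), v.var()
            return g * (v - mu) / np.sqrt(var + eps) + b

        x = h[0]
        qkv = x @ P["block0.Wqkv"] + P["block0.bqkv"]
        q, k, v = qkv[:, :6], qkv[:, 6:12], qkv[:, 12:]
        att = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                att[i, j] = q[i] @ k[j] / np.sqrt(6)
        att = np.exp(att - att.max(axis=1, keepdims=True))
        att /= att.sum(axis=1, keepdims=True)
        msa = (att @ v) @ P["block0.Wo"] + P["block0.bo"]
        u = np.stack([
            ln(r, P["block0.ln1.g"], P["block0.ln1.b"]) for r in (x + msa)
        ])
        ff = np.maximum(u @ P["block0.W1"] + P["block0.b1"], 0) @ P["block0.W2"] + P["block0.b2"]
        ref = np.stack([
            ln(r, P["block0.ln2.g"], P["block0.ln2.b"]) for r in (u + ff)
        ])
        out = m.encoder_block(h, 0)
        assert np.allclose(out[0], ref, atol=1e-10)


class TestEncoderSharing:
    def test_identical_channels_get_identical_representations(self, rng):
        m = Delayformer(tiny_model_config(), seed=0)
        win = rng.normal(size=(1, 32, 6))
        win[:, :, 3] = win[:, :, 0]
        z = m.encode(m.embed_patches(m.tokenize(win)))
        assert np.array_equal(z[0], z[3])

    def test_channel_swap_swaps_representations(self, rng):
        m = Delayformer(tiny_model_config(), seed=0)
        win = rng.normal(size=(2, 32, 6))
        swapped = win[:, :, [1, 0, 2, 3, 4, 5]]
        z = m.encode(m.embed_patches(m.tokenize(win)))
        z2 = m.encode(m.embed_patches(m.tokenize(swapped)))
        z = z.reshape(2, 6, 18, 16)
        z2 = z2.reshape(2, 6, 18, 16)
        assert np.array_equal(z2[:, 0], z[:, 1])
        assert np.array_equal(z2[:, 1], z[:, 0])

    def test_single_encoder_object_for_all_channels(self):
        # weight sharing is by parameter identity: there is exactly one set
        # of encoder parameters, not per-channel copies
        m = Delayformer(tiny_model_config(), seed=0)
        block_keys = [k for k in m.params if k.startswith("block")]
        assert len(block_keys) == 12 * m.config.n_layers
        assert not any("channel" in k for k in m.params)


class TestDecoder:
    def test_zero_representation_returns_bias(self):
        m = Delayformer(tiny_model_config(), seed=0)
        m.params["head.b"][2] = np.arange(8, dtype=np.float32)
        out = m.decode_channel(np.zeros((18, 16)), 2)
        assert np.array_equal(out, np.arange(8))

    def test_independent_head_parameter_count(self):
        cfg = tiny_model_config()
        m = Delayformer(cfg, seed=0)
        F = cfg.n_tokens * cfg.D
        assert m.params["head.W"].shape == (6, F, 8)
        head_params = m.params["head.W"].size + m.params["head.b"].size
        assert head_params == cfg.N * (F + 1) * cfg.H

    def test_shared_heads_coincide(self, rng):
        m = Delayformer(tiny_model_config(decoder_mode="shared"), seed=0)
        z = rng.normal(size=(18, 16)).astype(np.float32)
        assert np.array_equal(m.decode_channel(z, 0), m.decode_channel(z, 5))

    def test_unknown_channel_rejected(self):
        m = Delayformer(tiny_model_config(), seed=0)
        with pytest.raises(IndexError):
            m.decode_channel(np.zeros((18, 16)), 6)


class TestForward:
    def test_shape_contract(self, rng):
        cfg = ModelConfig(W=96, H=96, N=30, L=49, p1=6, p2=7, D=16, n_layers=1, n_heads=2, ff_dim=16)
        m = Delayformer(cfg, seed=0)
        out = m.forward(rng.normal(size=(2, 96, 30)))
        assert out.shape == (2, 96, 30)

    def test_zero_input_zero_heads_gives_bias(self):
        m = Delayformer(tiny_model_config(), seed=0)
        m.params["head.W"][:] = 0
        m.params["head.b"][:] = np.arange(6, dtype=np.float32)[:, None]
        out = m.forward(np.zeros((2, 32, 6)))
        assert np.allclose(out, np.broadcast_to(np.arange(6), (2, 8, 6)))

    def test_channel_permutation_with_permuted_heads(self, rng):
        m = Delayformer(tiny_model_config(), seed=0)
        x = rng.normal(size=(3, 32, 6))
        perm = np.array([2, 0, 5, 1, 3, 4])
        base = m.forward(x)
        m2 = m.copy()
        m2.params["head.W"] = m.params["head.W"][perm]
        m2.params["head.b"] = m.params["head.b"][perm]
        out = m2.forward(x[:, :, perm])
        assert np.array_equal(out, base[:, :, perm])

    def test_wrong_window_length_names_axis(self, rng):
        m = Delayformer(tiny_model_config(), seed=0)
        with pytest.raises(ValueError, match="window axis"):
            m.forward(rng.normal(size=(2, 30, 6)))
        with pytest.raises(ValueError, match="channel axis"):
            m.forward(rng.normal(size=(2, 32, 4)))


class TestPersistenceOfWeights:
    def test_same_seed_same_outputs(self, rng):
        x = rng.normal(size=(2, 32, 6))
        a = Delayformer(tiny_model_config(), seed=11)
        b = Delayformer(tiny_model_config(), seed=11)
        assert np.array_equal(a.forward(x), b.forward(x))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        m = Delayformer(tiny_model_config(), seed=3)
        x = rng.normal(size=(1, 32, 6))
        m.save(tmp_path / "ckpt")
        m2 = Delayformer.load(tmp_path / "ckpt")
        assert m2.config == m.config
        assert np.array_equal(m.forward(x), m2.forward(x))
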