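"""Normalization, the channel-independent loss, and the training loops."""

import numpy as np
import pytest

from delayformer.embedding import make_windows
from delayformer.model import Delayformer
from delayformer.series import MultivariateSeries
from delayformer.training import (
    TrainConfig,
    ci_loss,
    finetune,
    fit_normalizer,
    pretrain_multi,
    seed_streams,
    train,
)

from conftest import tiny_model_config


def _pairs(series, W=32, H=8, stride=4):
    return make_windows(series, W, H, stride)


@pytest.fixture
def norm_small(lorenz_small):
    return fit_normalizer(lorenz_small).apply_series(lorenz_small)


class TestNormalizer:
    def test_constant_channel_gets_floor_std(self):
        s = MultivariateSeries(np.full((10, 2), 5.0))
        stats = fit_normalizer(s)
        assert np.allclose(stats.mean, 5.0)
        assert np.allclose(stats.std, 1e-8)

    def test_roundtrip(self, lorenz_small):
        stats = fit_normalizer(lorenz_small)
        v = lorenz_small.values
        assert np.allclose(stats.invert(stats.apply(v)), v, atol=1e-10)

    def test_zscored_split_is_standardized(self, lorenz_small):
        stats = fit_normalizer(lorenz_small)
        z = stats.apply(lorenz_small.values)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1, atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.zeros((0, 3)))


class TestCiLoss:
    def test_zero_at_equality(self, rng):
        x = rng.normal(size=(2, 3, 4))
        assert ci_loss(x, x) == 0.0

    def test_hand_example(self):
        assert ci_loss(np.array([[[0.0], [2.0]]]), np.array([[[1.0], [1.0]]])) == 1.0

    def test_matches_brute_force_triple_loop(self, rng):
        p = rng.normal(size=(3, 4, 2))
        t = rng.normal(size=(3, 4, 2))
        acc = 0.0
        for b in range(3):
            for h in range(4):
                for k in range(2):
                    acc += (p[b, h, k] - t[b, h, k]) ** 2
        assert ci_loss(p, t) == pytest.approx(acc / 24, rel=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            ci_loss(rng.normal(size=(2, 3, 4)), rng.normal(size=(2, 3, 5)))


class TestTrain:
    def test_zero_epochs_returns_initialized_model(self, norm_small):
        pairs = _pairs(norm_small)
        m = Delayformer(tiny_model_config(), seed=0)
        before = {k: v.copy() for k, v in m.params.items()}
        res = train(m, pairs[:10], pairs[10:12], TrainConfig(max_epochs=0))
        assert res.history == []
        assert all(np.array_equal(before[k], m.params[k]) for k in before)

    def test_empty_training_data_rejected(self):
        m = Delayformer(tiny_model_config(), seed=0)
        with pytest.raises(ValueError):
            train(m, [], [], TrainConfig())

    def test_fixed_seed_bitwise_reproducible(self, norm_small):
        pairs = _pairs(norm_small)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, batch_size=8, seed=5)
        runs = []
        for _ in range(2):
            m = Delayformer(tiny_model_config(dropout=0.1), seed=9)
            res = train(m, pairs[:30], pairs[30:36], cfg)
            runs.append((res.best_val_mse, {k: v.copy() for k, v in m.params.items()}))
        assert runs[0][0] == runs[1][0]
        assert all(np.array_equal(runs[0][1][k], runs[1][1][k]) for k in runs[0][1])

    def test_best_checkpoint_not_worse_than_init(self, norm_small):
        pairs = _pairs(norm_small)
        m = Delayformer(tiny_model_config(), seed=1)
        res = train(m, pairs[:30], pairs[30:36],
                    TrainConfig(learning_rate=1e-3, max_epochs=3, batch_size=8, seed=0))
        # history[-(patience)] epochs ran; restored weights are the best seen,
        # which can never exceed the epoch-0 validation loss
        from delayformer.training import stack_windows, predict_batched
        Xv, Yv = stack_windows(pairs[30:36])
        assert ci_loss(predict_batched(m, Xv), Yv) <= res.history[0]["val_mse"] + 1e-9

    def test_seed_streams_are_independent(self):
        a = seed_streams(7, 3)
        b = seed_streams(7, 3)
        c = seed_streams(8, 3)
        for x, y in zip(a, b):
            assert x.random() == y.random()
        assert a[0].random() != c[0].random()

    def test_batch_order_seed_changes_results(self, norm_small):
        pairs = _pairs(norm_small)

        def run(seed):
            m = Delayformer(tiny_model_config(), seed=9)
            train(m, pairs[:30], pairs[30:36],
                  TrainConfig(learning_rate=1e-3, max_epochs=1, batch_size=8, seed=seed))
            return m.params["embed.W"].copy()

        assert not np.array_equal(run(1), run(2))

    def test_normalization_absorbs_channel_affine_transforms(self, lorenz_small):
        # scaling channel k by a_k and shifting by b_k must not change
        # normalized-scale predictions (z-scoring absorbs the transform)
        scale = np.array([2.0, 0.5, 3.0, 1.0, 10.0, 0.1])
        shift = np.array([1.0, -5.0, 0.0, 2.0, -1.0, 0.3])
        transformed = MultivariateSeries(lorenz_small.values * scale + shift)

        preds = []
        for series in (lorenz_small, transformed):
            z = fit_normalizer(series).apply_series(series)
            pairs = _pairs(z)
            m = Delayformer(tiny_model_config(dtype="float64"), seed=4)
            train(m, pairs[:20], [],
                  TrainConfig(learning_rate=1e-3, max_epochs=1, batch_size=8, seed=0))
            from delayformer.training import stack_windows
            X, _ = stack_windows(pairs[20:24])
            preds.append(m.forward(X))
        assert np.allclose(preds[0], preds[1], atol=1e-6)

    def test_nan_loss_aborts_with_hint(self, norm_small):
        pairs = _pairs(norm_small)
        m = Delayformer(tiny_model_config(), seed=0)
        m.params["embed.W"][:] = 1e30  # force immediate overflow
        with np.errstate(all="ignore"), pytest.raises((RuntimeError, FloatingPointError)):
            train(m, pairs[:10], [], TrainConfig(learning_rate=1.0, max_epochs=1, batch_size=4))


class TestPretrainFinetune:
    def _datasets(self, lorenz_small, n=3):
        out = []
        for i in range(n):
            shifted = MultivariateSeries(np.roll(lorenz_small.values, 37 * i, axis=0))
            z = fit_normalizer(shifted).apply_series(shifted)
            pairs = _pairs(z)
            out.append((pairs[:20], pairs[20:24]))
        return out

    def test_requires_shared_decoder(self, lorenz_small):
        m = Delayformer(tiny_model_config(decoder_mode="independent"), seed=0)
        with pytest.raises(ValueError, match="shared"):
            pretrain_multi(m, self._datasets(lorenz_small), TrainConfig(max_epochs=1))

    def test_single_dataset_reduces_training_loss(self, lorenz_small):
        ds = self._datasets(lorenz_small, 1)
        m = Delayformer(tiny_model_config(decoder_mode="shared"), seed=0)
        res = pretrain_multi(
            m, ds, TrainConfig(learning_rate=1e-3, max_epochs=3, batch_size=8, seed=0)
        )
        assert res.history[-1]["train_loss"] < res.history[0]["train_loss"]

    def test_channel_counts_may_differ(self, lorenz_small):
        full = fit_normalizer(lorenz_small).apply_series(lorenz_small)
        three = full.select_channels([0, 1, 2])
        datasets = [(_pairs(full)[:10], []), (_pairs(three)[:10], [])]
        m = Delayformer(tiny_model_config(decoder_mode="shared"), seed=0)
        res = pretrain_multi(
            m, datasets, TrainConfig(learning_rate=1e-3, max_epochs=1, batch_size=4, seed=0)
        )
        assert len(res.history) == 1

    def test_geometry_mismatch_rejected(self, norm_small):
        short = make_windows(norm_small, 16, 8, 4)
        m = Delayformer(tiny_model_config(decoder_mode="shared"), seed=0)
        with pytest.raises(ValueError, match="geometry"):
            pretrain_multi(m, [(short[:5], [])], TrainConfig(max_epochs=1))

    def test_finetune_fraction_selects_most_recent_windows(self, norm_small, monkeypatch):
        pairs = _pairs(norm_small)
        m = Delayformer(tiny_model_config(decoder_mode="shared"), seed=0)
        seen = {}
        import delayformer.training as tr

        def fake_train(model, train_pairs, val_pairs, config):
            seen["starts"] = [p.start_index for p in train_pairs]
            return tr.TrainResult(model=model)

        monkeypatch.setattr(tr, "train", fake_train)
        tr.finetune(m, pairs, 0.25, TrainConfig(max_epochs=1))
        expect = [p.start_index for p in pairs[-int(round(0.25 * len(pairs))):]]
        assert seen["starts"] == expect

    def test_zero_window_fraction_rejected(self, norm_small):
        pairs = _pairs(norm_small)
        m = Delayformer(tiny_model_config(decoder_mode="shared"), seed=0)
        with pytest.raises(ValueError):
            finetune(m, pairs, 1e-6, TrainConfig(max_epochs=1))
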