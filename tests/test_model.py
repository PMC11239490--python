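"""Classifier architecture, losses, augmentation, calibration, training."""

import numpy as np
import pytest

from glycrunch.model import (
    AugmentConfig,
    ModelConfig,
    TrainConfig,
    augment,
    augment_batch,
    build_model,
    calibrate_and_predict,
    classification_loss,
    distance_loss,
    featurize,
    load_model,
    save_model,
    softmax,
    stack_features,
    train,
)
from glycrunch.spectra import BIN_WIDTH, BinnedSpectrum, Spectrum, default_meta

TINY = ModelConfig(
    n_classes=3, n_bins=40, conv_channels=3, kernel_size=3, dilations=(1, 2),
    pool_kernel=4, trunk_dim=8, embed_dim=4, hidden_dims=(6,), dropout=0.0,
)


def tiny_batch(rng, b=2, n_bins=40):
    return {
        "intensity": rng.random((b, n_bins)).astype(np.float32) / 10,
        "remainder": rng.random((b, n_bins)).astype(np.float32),
        "precursor": (rng.random(b) * 1000).astype(np.float32),
        "rt": rng.random(b).astype(np.float32),
        "cats": rng.integers(0, 2, (b, 5)),
    }


class TestArchitecture:
    def test_output_dimension_is_class_count(self, rng):
        model = build_model(TINY, rng)
        logits = model.forward(tiny_batch(rng, b=5))
        assert logits.shape == (5, TINY.n_classes)

    def test_forward_sensitive_to_single_bin(self, rng):
        model = build_model(TINY, rng)
        batch = tiny_batch(rng)
        l0 = model.forward(batch)
        batch2 = {k: v.copy() for k, v in batch.items()}
        batch2["intensity"][0, 7] += 0.3
        l1 = model.forward(batch2)
        assert np.abs(l1[0] - l0[0]).max() > 0
        np.testing.assert_allclose(l1[1], l0[1], atol=1e-6)

    def test_eval_passes_are_deterministic(self, rng):
        cfg = ModelConfig(
            n_classes=3, n_bins=40, conv_channels=3, kernel_size=3, dilations=(1,),
            pool_kernel=4, trunk_dim=8, embed_dim=4, hidden_dims=(6,), dropout=0.5,
        )
        model = build_model(cfg, rng)
        model.set_dropout_rng(np.random.default_rng(0))
        batch = tiny_batch(rng)
        np.testing.assert_array_equal(model.forward(batch), model.forward(batch))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=1)
        with pytest.raises(ValueError):
            ModelConfig(n_classes=3, trunk_dim=0)

    def test_gradients_match_finite_differences(self, rng):
        import glycrunch.model.layers as layers_mod
        import glycrunch.model.network as network_mod

        old = layers_mod.DTYPE
        layers_mod.DTYPE = network_mod.DTYPE = np.float64
        try:
            model = build_model(TINY, np.random.default_rng(0))
            batch = tiny_batch(np.random.default_rng(1))
            batch = {k: v.astype(np.float64) if v.dtype.kind == "f" else v
                     for k, v in batch.items()}
            y = np.array([0, 2])
            d = rng.random((3, 3))
            np.fill_diagonal(d, 0)

            def loss():
                return classification_loss(model.forward(batch), y, d, d)[0]["total"]

            model.zero_grad()
            comps, dl = classification_loss(model.forward(batch), y, d, d)
            model.backward(dl)
            check_rng = np.random.default_rng(2)
            for p in model.params():
                flat = p.value.reshape(-1)
                for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    eps, old_v = 1e-6, flat[i]
                    flat[i] = old_v + eps
                    lp = loss()
                    flat[i] = old_v - eps
                    lm = loss()
                    flat[i] = old_v
                    num = (lp - lm) / (2 * eps)
                    ana = p.grad.reshape(-1)[i]
                    assert num == pytest.approx(ana, rel=1e-3, abs=1e-7), p.name
        finally:
            layers_mod.DTYPE = network_mod.DTYPE = old

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = build_model(TINY, rng)
        path = tmp_path / "model.npz"
        save_model(model, path, library=["a", "b", "c"])
        loaded, labels = load_model(path)
        assert labels == ["a", "b", "c"]
        batch = tiny_batch(rng)
        np.testing.assert_allclose(model.forward(batch), loaded.forward(batch), atol=1e-6)


class TestDistanceLoss:
    def test_all_mass_on_true_class_gives_zero(self):
        probs = np.array([0.0, 1.0, 0.0])
        dist = np.array([0.7, 0.0, 0.3])
        assert distance_loss(probs, dist) == 0.0

    def test_constant_distance_for_any_distribution(self, rng):
        probs = rng.dirichlet(np.ones(6), size=4)
        dist = np.full((4, 6), 0.42)
        assert distance_loss(probs, dist) == pytest.approx(0.42)

    def test_uniform_over_binary_distances(self):
        probs = np.full(4, 0.25)
        dist = np.array([0.0, 0.0, 1.0, 1.0])
        assert distance_loss(probs, dist) == pytest.approx(0.5)

    def test_bounded_by_unit_distances(self, rng):
        probs = rng.dirichlet(np.ones(5), size=8)
        dist = rng.random((8, 5))
        assert 0.0 <= distance_loss(probs, dist) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_loss(np.ones(3) / 3, np.ones(4))

    def test_zero_distances_reduce_total_to_polyloss(self, rng):
        logits = rng.normal(size=(4, 5))
        y = np.array([0, 1, 2, 3])
        zeros = np.zeros((5, 5))
        with_d, grad_d = classification_loss(logits, y, zeros, zeros)
        without, grad_0 = classification_loss(logits, y, None, None)
        assert with_d["total"] == pytest.approx(without["total"])
        np.testing.assert_allclose(grad_d, grad_0, atol=1e-12)


class TestAugment:
    def _spectrum(self):
        return Spectrum(
            peaks=np.array([[100.0, 0.5], [200.0, 0.2], [300.0, 0.3]]),
            precursor_mz=512.3, rt=10.0,
        )

    def _zero_cfg(self):
        return AugmentConfig(
            peak_drop_frac=0.0, intensity_jitter_sd=0.0, new_peak_rate=0.0,
            adduct_prob=0.0, precursor_jitter=0.0, rt_jitter=0.0,
        )

    def test_all_rates_zero_is_identity(self, rng):
        s = self._spectrum()
        out = augment(s, self._zero_cfg(), rng)
        np.testing.assert_array_equal(out.peaks, s.peaks)
        assert out.precursor_mz == s.precursor_mz and out.rt == s.rt

    def test_reproducible_under_fixed_seed(self):
        s = self._spectrum()
        a = augment(s, AugmentConfig(), np.random.default_rng(99))
        b = augment(s, AugmentConfig(), np.random.default_rng(99))
        np.testing.assert_array_equal(a.peaks, b.peaks)
        assert a.precursor_mz == b.precursor_mz

    def test_precursor_jitter_bounded(self):
        s = self._spectrum()
        cfg = AugmentConfig(adduct_prob=0.0)
        rng = np.random.default_rng(0)
        deltas = [
            abs(augment(s, cfg, rng).precursor_mz - s.precursor_mz) for _ in range(10000)
        ]
        assert max(deltas) <= 0.5

    def test_batch_augmentation_renormalizes(self, rng):
        batch = {
            "intensity": rng.dirichlet(np.ones(50), size=3).astype(np.float32),
            "remainder": rng.random((3, 50)).astype(np.float32),
            "precursor": np.full(3, 500.0, np.float32),
            "rt": rng.random(3).astype(np.float32),
            "cats": np.zeros((3, 5), np.int64),
        }
        out = augment_batch(batch, AugmentConfig(), rng)
        np.testing.assert_allclose(out["intensity"].sum(1), 1.0, atol=1e-5)


class TestCalibration:
    def _binned(self, rng, n_bins=40):
        return BinnedSpectrum(
            intensities=rng.dirichlet(np.ones(n_bins)),
            remainders=rng.random(n_bins) * BIN_WIDTH,
            rt_norm=0.4, precursor_mz=600.0, meta=default_meta(),
        )

    def test_uniform_logits_stay_uniform_under_any_factor(self):
        for factor in (0.5, 1.0, 1.15, 3.0):
            p = softmax(np.zeros((1, 7)) / factor)
            np.testing.assert_allclose(p, 1 / 7)

    def test_platt_division_preserves_argmax(self, rng):
        logits = rng.normal(size=20)
        assert np.argmax(softmax(logits / 1.15)) == np.argmax(softmax(logits))

    def test_single_round_without_augmentation_is_plain_softmax(self, rng):
        model = build_model(TINY, rng)
        binned = self._binned(rng)
        labels = ["g0", "g1", "g2"]
        preds = calibrate_and_predict(
            model, binned, labels, platt_factor=1.15, tta_rounds=1, k=3, acfg=None
        )
        feats = stack_features([featurize(binned)])
        expected = softmax(model.forward(feats)[0] / 1.15)
        for label, score in preds:
            assert score == pytest.approx(expected[labels.index(label)], abs=1e-6)

    def test_k_clipped_to_class_count(self, rng):
        model = build_model(TINY, rng)
        preds = calibrate_and_predict(
            model, self._binned(rng), ["a", "b", "c"], k=25, tta_rounds=1
        )
        assert len(preds) == 3


@pytest.fixture(scope="module")
def toy():
    """Five easily separable classes by precursor mass and spectrum."""
    rng = np.random.default_rng(0)
    n_per, n_bins, n_classes = 16, 40, 5
    templates = rng.random((n_classes, n_bins)) * (rng.random((n_classes, n_bins)) < 0.2)
    templates /= templates.sum(1, keepdims=True)
    feats, y, sample = [], [], []
    for c in range(n_classes):
        for i in range(n_per):
            inten = templates[c] * rng.uniform(0.7, 1.3, n_bins)
            inten /= inten.sum()
            feats.append({
                "intensity": inten.astype(np.float32),
                "remainder": (templates[c] > 0).astype(np.float32) * 0.5,
                "precursor": np.float32(300.0 + 100 * c),
                "rt": np.float32(0.1 + 0.15 * c),
                "cats": np.zeros(5, np.int64),
            })
            y.append(c)
            sample.append(i)
    data = stack_features(feats)
    data["y"] = np.array(y)
    sample = np.array(sample)
    data["train_idx"] = np.nonzero(sample < 12)[0]
    data["test_idx"] = np.nonzero(sample >= 12)[0]
    return data


class TestTraining:
    def test_loss_finite_and_decreasing(self, toy):
        cfg = ModelConfig(
            n_classes=5, n_bins=40, conv_channels=4, kernel_size=3,
            dilations=(1, 2, 4), pool_kernel=4, trunk_dim=16, embed_dim=8,
            hidden_dims=(16,), dropout=0.1,
        )
        model = build_model(cfg, np.random.default_rng(0))
        hist = train(model, toy, TrainConfig(epochs=6, lr=2e-3, batch_size=16, seed=0))
        assert np.isfinite(hist["train_loss"]).all()
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert hist["val_acc"][-1] >= 0.6

    def test_empty_dataset_rejected(self, toy):
        model = build_model(TINY, np.random.default_rng(0))
        bad = dict(toy)
        bad["train_idx"] = np.array([], dtype=int)
        with pytest.raises(ValueError):
            train(model, bad, TrainConfig(epochs=1))

    def test_single_class_rejected(self, toy):
        model = build_model(TINY, np.random.default_rng(0))
        bad = dict(toy)
        bad["train_idx"] = np.nonzero(toy["y"] == 0)[0]
        with pytest.raises(ValueError):
            train(model, bad, TrainConfig(epochs=1))

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_patience=12, early_stop=12)
        with pytest.raises(ValueError):
            TrainConfig(lr=-1.0)
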