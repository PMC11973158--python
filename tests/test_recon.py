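"""Data consistency, training schedule and inference behaviour."""

import numpy as np
import pytest

from fourierpd.kspace import fft2c, ifft2c, make_varden1d_mask, undersample
from fourierpd.models import FourierPD, ReconModelConfig
from fourierpd.recon import (
    MeasuredSample,
    TrainConfig,
    data_consistency,
    learning_rate_at,
    load_checkpoint,
    make_measured_sample,
    reconstruct,
    save_checkpoint,
    train,
)


class TestDataConsistency:
    def test_acquired_locations_match_measured_exactly(self, phantom64, mask64, rng):
        measured = undersample(fft2c(phantom64), mask64)
        pred = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        out = data_consistency(pred, measured, mask64)
        err = np.abs((fft2c(out) - measured) * mask64.grid).max()
        assert err < 1e-10

    def test_all_ones_mask_bypasses_prediction(self, phantom64, rng):
        ones = make_varden1d_mask((64, 64), 1.0, seed=0)
        measured = fft2c(phantom64)
        pred = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        out = data_consistency(pred, measured, ones)
        assert np.abs(out - ifft2c(measured)).max() < 1e-12

    def test_ground_truth_is_fixed_point(self, phantom64, mask64):
        measured = undersample(fft2c(phantom64), mask64)
        out = data_consistency(phantom64, measured, mask64)
        assert np.abs(out - phantom64).max() < 1e-10

    def test_idempotent(self, phantom64, mask64, rng):
        measured = undersample(fft2c(phantom64), mask64)
        pred = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        once = data_consistency(pred, measured, mask64)
        twice = data_consistency(once, measured, mask64)
        assert np.abs(twice - once).max() < 1e-12

    def test_shape_mismatch_raises(self, mask64):
        with pytest.raises(ValueError):
            data_consistency(np.ones((32, 32), complex), np.ones((64, 64), complex), mask64)


class TestSchedule:
    def test_stepped_learning_rate_values(self):
        cfg = TrainConfig()  # reference recipe: 1e-4, decay x0.1 every 50 epochs
        assert learning_rate_at(1, cfg) == pytest.approx(1e-4)
        assert learning_rate_at(50, cfg) == pytest.approx(1e-4)
        assert learning_rate_at(51, cfg) == pytest.approx(1e-5)
        assert learning_rate_at(100, cfg) == pytest.approx(1e-5)
        assert learning_rate_at(101, cfg) == pytest.approx(1e-6)

    def test_reference_profile_constants(self):
        cfg = TrainConfig()
        assert (cfg.epochs, cfg.batch_size) == (100, 1)
        assert (cfg.beta1, cfg.beta2, cfg.eps) == (0.9, 0.999, 1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lr=-1.0)


class TestTraining:
    def test_single_sample_overfit_reduces_loss(self, phantom64, mask64):
        model = FourierPD(ReconModelConfig(n_iterations=2, n_filters=4, seed=0))
        ds = [make_measured_sample(phantom64, mask64)]
        res = train(model, ds, TrainConfig(epochs=60, lr=1e-3, seed=0))
        assert res.loss_history[-1] < res.loss_history[0]
        # smoothed trajectory is non-increasing on a noiseless overfit run
        smooth = np.convolve(res.loss_history, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(smooth) < 1e-4)

    def test_seeded_training_is_reproducible(self, phantom64, mask64):
        ds = [make_measured_sample(phantom64, mask64)]
        losses = []
        for _ in range(2):
            model = FourierPD(ReconModelConfig(n_iterations=2, n_filters=4, seed=0))
            res = train(model, ds, TrainConfig(epochs=1, lr=1e-3, seed=0))
            losses.append(res.loss_history[0])
        assert losses[0] == losses[1]

    def test_empty_dataset_rejected(self):
        model = FourierPD(ReconModelConfig(n_iterations=1, n_filters=2, seed=0))
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(epochs=1))

    def test_measured_sample_contract(self, phantom64, mask64):
        with pytest.raises(ValueError):
            MeasuredSample(measured_k=fft2c(phantom64), mask=mask64, target=phantom64)


class TestReconstruct:
    def test_untrained_zero_weight_model_returns_zero_filled(self, phantom64, mask64):
        model = FourierPD(ReconModelConfig(n_iterations=3, n_filters=8, seed=0))
        model.zero_weights()
        measured = undersample(fft2c(phantom64), mask64)
        out = reconstruct(model, measured, mask64)
        assert np.abs(out - ifft2c(measured)).max() < 1e-12

    def test_output_k_space_matches_measured_on_mask(self, phantom64, mask64):
        model = FourierPD(ReconModelConfig(n_iterations=2, n_filters=4, seed=1))
        measured = undersample(fft2c(phantom64), mask64)
        out = reconstruct(model, measured, mask64)
        assert np.abs((fft2c(out) - measured) * mask64.grid).max() < 1e-10

    def test_checkpoint_roundtrip(self, tmp_path, phantom64, mask64):
        model = FourierPD(ReconModelConfig(n_iterations=2, n_filters=4, seed=3))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, mask=mask64, extra={"note": "test"})
        loaded, meta = load_checkpoint(path)
        assert meta["model"]["n_iterations"] == 2
        assert meta["mask"]["kind"] == "varden1d"
        measured = undersample(fft2c(phantom64), mask64)
        assert np.array_equal(
            reconstruct(model, measured, mask64), reconstruct(loaded, measured, mask64)
        )
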