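"""Sequence regressor: architecture, gradients, normalization, training."""

import warnings

import numpy as np
import pytest

from gaitforce.containers import Condition
from gaitforce.nn import BiLSTMLayer, DenseLayer, Network, mse_loss
from gaitforce.rnn import (
    GRFNet,
    RNNSpec,
    TrainOptions,
    apply_norm,
    build_rnn,
    compute_norm_stats,
    features_from_steps,
    finetune_subject,
    predict_rnn,
    targets_from_steps,
    train_rnn,
)
from gaitforce.synthetic import ideal_step_dataset


@pytest.fixture(scope="module")
def tiny_ds():
    ds, _ = ideal_step_dataset(
        n_subjects=2,
        conditions=[Condition(2.6, 0.0), Condition(3.4, 0.0)],
        steps_per_combo=3,
        noise_pr=0.3,
        seed=17,
    )
    return ds


@pytest.fixture(scope="module")
def tiny_xy(tiny_ds):
    X = features_from_steps(tiny_ds)
    Y = targets_from_steps(tiny_ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = compute_norm_stats(X)
    return X, Y, stats


class TestArchitecture:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            RNNSpec(input_channels=7)
        with pytest.raises(ValueError):
            RNNSpec(dropout=(1.0, 0.2))
        with pytest.raises(ValueError):
            RNNSpec(bilstm_nodes=(0, 10))

    def test_forward_on_zeros_is_finite_with_right_shape(self):
        model = build_rnn(RNNSpec.reduced(), seed=1)
        out = model.forward(np.zeros((3, 101, 8)))
        assert out.shape == (3, 101, 2)
        assert np.all(np.isfinite(out))

    def test_same_seed_builds_identical_networks(self):
        x = np.random.default_rng(0).normal(size=(2, 101, 8))
        a = build_rnn(RNNSpec.reduced(), seed=9).forward(x)
        b = build_rnn(RNNSpec.reduced(), seed=9).forward(x)
        assert np.array_equal(a, b)

    def test_six_channel_ablation_variant(self):
        model = build_rnn(RNNSpec.reduced(input_channels=6), seed=1)
        out = model.forward(np.zeros((2, 101, 6)))
        assert out.shape == (2, 101, 2)

    def test_channel_mismatch_raises(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(input_channels=6), seed=0)
        with pytest.raises(ValueError, match="channel"):
            predict_rnn(model, stats, X)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        net = Network(
            [
                BiLSTMLayer(3, 4, rng),
                DenseLayer(8, 5, rng, tanh=True),
                DenseLayer(5, 2, rng, tanh=False),
            ]
        )
        x = rng.standard_normal((7, 2, 3))
        y = rng.standard_normal((7, 2, 2))
        net.zero_grad()
        loss, g = mse_loss(net.forward(x), y)
        net.backward(g)
        for p, gr in zip(net.params(), net.grads()):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            l1, _ = mse_loss(net.forward(x), y)
            p[idx] = orig - eps
            l2, _ = mse_loss(net.forward(x), y)
            p[idx] = orig
            num = (l1 - l2) / (2 * eps)
            assert abs(num - gr[idx]) < 1e-5 * max(1.0, abs(num))


class TestNormalization:
    def test_training_split_becomes_standard_normal(self, tiny_xy):
        X, _, stats = tiny_xy
        Z = apply_norm(stats, X)
        nonconst = X.std(axis=(0, 1)) > 1e-12
        assert np.abs(Z.mean(axis=(0, 1))[nonconst]).max() < 1e-10
        assert np.abs(Z.std(axis=(0, 1))[nonconst] - 1.0).max() < 1e-10

    def test_stats_do_not_transfer_across_splits(self, tiny_ds):
        a = tiny_ds.filter(subjects=[tiny_ds.subjects[0]])
        b = tiny_ds.filter(subjects=[tiny_ds.subjects[1]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats_a = compute_norm_stats(features_from_steps(a))
        Zb = apply_norm(stats_a, features_from_steps(b))
        assert np.abs(Zb.mean(axis=(0, 1))).max() > 1e-3

    def test_constant_channel_warns_and_uses_unit_sd(self, tiny_xy):
        X, _, _ = tiny_xy
        with pytest.warns(RuntimeWarning, match="constant"):
            stats = compute_norm_stats(X)  # slope channel is constant (level only)
        assert stats.std[7] == 1.0

    def test_mass_channel_varies_across_subjects(self, tiny_xy):
        X, _, _ = tiny_xy
        assert X[..., 5].std() > 0


class TestTraining:
    def test_single_epoch_records_one_history_entry(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(), seed=2)
        hist = train_rnn(model, X, Y, stats, TrainOptions(max_epochs=1))
        assert len(hist["train_loss"]) == 1

    def test_overfits_tiny_dataset(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(dropout=(0.0, 0.0)), seed=3)
        opts = TrainOptions(
            max_epochs=150, learning_rate=3e-3, batch_size=8, val_fraction=0.0
        )
        hist = train_rnn(model, X, Y, stats, opts)
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        pred = predict_rnn(model, stats, X)
        rmse_v = np.sqrt(np.mean((pred[:, 0, :] - Y[:, :, 0]) ** 2))
        assert rmse_v < 0.05  # BW

    def test_nonfinite_loss_aborts_with_diagnostics(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(), seed=2)
        Y_bad = Y.copy()
        Y_bad[0, 0, 0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            train_rnn(
                model, X, Y_bad, stats,
                TrainOptions(max_epochs=2, val_fraction=0.0),
            )

    def test_inference_is_deterministic(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(), seed=4)
        assert np.array_equal(predict_rnn(model, stats, X), predict_rnn(model, stats, X))

    def test_dropout_only_active_in_training(self, tiny_xy):
        X, _, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(dropout=(0.5, 0.5)), seed=4)
        Xn = apply_norm(stats, X[:2]).transpose(1, 0, 2)
        rng = np.random.default_rng(0)
        train_out = model.net.forward(Xn, train=True, rng=rng)
        infer_out = model.net.forward(Xn, train=False)
        assert not np.allclose(train_out, infer_out)
        assert np.array_equal(infer_out, model.net.forward(Xn, train=False))


class TestFinetune:
    def test_invalid_fraction_rejected(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(), seed=0)
        keys = ["c"] * X.shape[0]
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                finetune_subject(model, stats, X, Y, keys, fraction=bad)

    def test_split_is_disjoint_and_stratified(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(), seed=0)
        keys = (["a"] * 6) + (["b"] * 6)
        opts = TrainOptions(max_epochs=1, finetune_epochs=1)
        _, tune_idx, hold_idx = finetune_subject(
            model, stats, X, Y, keys, fraction=0.34, options=opts, seed=1
        )
        assert np.intersect1d(tune_idx, hold_idx).size == 0
        assert len(tune_idx) + len(hold_idx) == X.shape[0]
        assert any(i < 6 for i in tune_idx) and any(i >= 6 for i in tune_idx)

    def test_same_seed_same_selection(self, tiny_xy):
        X, Y, stats = tiny_xy
        model = build_rnn(RNNSpec.reduced(), seed=0)
        keys = ["a"] * X.shape[0]
        opts = TrainOptions(max_epochs=1, finetune_epochs=1)
        _, t1, _ = finetune_subject(model, stats, X, Y, keys, 0.25, opts, seed=7)
        _, t2, _ = finetune_subject(model, stats, X, Y, keys, 0.25, opts, seed=7)
        assert np.array_equal(t1, t2)


def test_save_load_round_trip(tmp_path, tiny_xy):
    X, _, stats = tiny_xy
    model = build_rnn(RNNSpec.reduced(), seed=11)
    prefix = str(tmp_path / "net")
    model.save(prefix)
    restored = GRFNet.load(prefix)
    assert np.array_equal(
        model.forward(X[:2]), restored.forward(X[:2])
    )
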