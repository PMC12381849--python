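"""Architectures, training protocol, determinism and grid search."""

import hashlib

import numpy as np
import pytest

from nmrsubstruct import nn
from nmrsubstruct.models import (ModelSpec, TrainingProtocol, accuracy_of,
                                 build_model, grid_search, load_model,
                                 predict, predict_on, split_train_test, take,
                                 train, TrainedModel)


def toy_dataset(n=120, m=5, max_len=6, noise=0.0, seed=0):
    """Separable by construction: class k lives at shift k+0.5 (scaled).

    A nearest-base-shift rule classifies this perfectly, so any model
    failing to fit it lacks capacity or training, not information.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, m, size=n)
    shift = y + 0.5 + rng.normal(0, noise, size=n)
    lengths = rng.integers(2, max_len + 1, size=n)
    seq = np.zeros((n, max_len))
    for i in range(n):
        seq[i, : lengths[i]] = np.sort(rng.uniform(0, m, size=lengths[i]))
        seq[i, 0] = shift[i]
    fixed = np.column_stack([
        shift,
        rng.integers(0, 5, size=n).astype(float),
        rng.uniform(0, 1, size=(n, 2)),
    ])
    features = {
        "fixed": fixed,
        "seq_shifts": seq,
        "seq_mults": np.zeros((n, max_len)),
        "lengths": lengths,
        "atom_index": np.arange(n),
        "record_index": np.arange(n),
    }
    return features, y


def weights_digest(net):
    h = hashlib.sha256()
    for layer in nn._expand(net.layers()):
        for name in sorted(layer.params):
            h.update(layer.params[name].tobytes())
    return h.hexdigest()


class TestBuildModel:
    def test_hybrid_parameter_count_matches_arithmetic(self):
        spec = ModelSpec(architecture="mlp_lstm", output_classes=6,
                         recurrent_units=50, mlp_widths=(100, 500),
                         fixed_hidden=64, head_widths=(128,))
        net = build_model(spec, fixed_dim=5, max_len=None)
        u, d = 50, 2
        lstm1 = 2 * (4 * u * (d + u) + 4 * u)          # two directions
        lstm2 = 2 * (4 * u * (2 * u + u) + 4 * u)      # stacked layer
        dense_v = (2 * u) * 100 + 100 + 100 * 500 + 500
        dense_f = 5 * 64 + 64
        head = (500 + 64) * 128 + 128 + 128 * 6 + 6
        assert nn.parameter_count(net.layers()) == (
            lstm1 + lstm2 + dense_v + dense_f + head
        )

    def test_hybrid_has_exactly_two_bidirectional_recurrent_layers(self):
        net = build_model(ModelSpec(architecture="mlp_lstm",
                                    output_classes=3), 4)
        recurrent = [l for l in net.layers()
                     if isinstance(l, nn.Bidirectional)]
        assert len(recurrent) == 2

    def test_cnn_pool_halves_length_rounding_up(self, rng):
        spec = ModelSpec(architecture="cnn", output_classes=3,
                         conv_blocks=((8, 3, 2),))
        net = build_model(spec, fixed_dim=4, max_len=9)
        seq = rng.standard_normal((2, 9, 2))
        h = seq
        for layer in net.blocks:
            h = layer.forward(h)
        assert h.shape[1] == 5  # ceil(9/2)

    def test_minimal_output_sums_to_one(self, rng):
        spec = ModelSpec(architecture="cnn", output_classes=2)
        net = build_model(spec, fixed_dim=4, max_len=6)
        probs = nn.softmax(net.forward(rng.standard_normal((3, 4)),
                                       rng.standard_normal((3, 6, 2))))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(architecture="cnn", output_classes=1)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(architecture="transformer")


class TestTrain:
    def test_zero_noise_separable_reaches_perfect_training_accuracy(self):
        features, y = toy_dataset(n=120, m=5, noise=0.0)
        spec = ModelSpec(architecture="cnn", output_classes=5, epochs=120,
                         batch_size=16, seed=0)
        net = build_model(spec, features["fixed"].shape[1],
                          features["seq_shifts"].shape[1])
        trained = train(net, features, y, spec)
        assert trained.history["accuracy"][-1] == 1.0

    def test_single_sample_memorized(self):
        features, y = toy_dataset(n=1, m=5)
        spec = ModelSpec(architecture="mlp_rnn", output_classes=5,
                         epochs=60, batch_size=1, seed=0)
        net = build_model(spec, features["fixed"].shape[1])
        train(net, features, y, spec)
        assert accuracy_of(net, features, y) == 1.0

    def test_same_seed_identical_final_weights(self):
        features, y = toy_dataset(n=40, m=3)
        digests = []
        for _ in range(2):
            spec = ModelSpec(architecture="mlp_lstm", output_classes=3,
                             epochs=3, batch_size=8, seed=11)
            net = build_model(spec, features["fixed"].shape[1])
            train(net, features, y, spec)
            digests.append(weights_digest(net))
        assert digests[0] == digests[1]

    def test_shape_mismatch_rejected_before_training(self):
        features, y = toy_dataset(n=30, m=3)
        spec = ModelSpec(architecture="cnn", output_classes=3, epochs=1)
        net = build_model(spec, features["fixed"].shape[1],
                          features["seq_shifts"].shape[1])
        with pytest.raises(ValueError):
            train(net, features, y[:-3], spec)

    def test_one_hot_targets_accepted_and_validated(self):
        features, y = toy_dataset(n=30, m=3)
        onehot = np.eye(3)[y]
        spec = ModelSpec(architecture="cnn", output_classes=3, epochs=2,
                         seed=0)
        net = build_model(spec, features["fixed"].shape[1],
                          features["seq_shifts"].shape[1])
        train(net, features, onehot, spec)
        bad = onehot.copy()
        bad[0] = 0.5
        with pytest.raises(ValueError):
            train(net, features, bad, spec)


class TestPredict:
    def test_rows_on_simplex_order_preserved(self):
        features, y = toy_dataset(n=50, m=4)
        spec = ModelSpec(architecture="cnn", output_classes=4, epochs=5,
                         seed=0)
        net = build_model(spec, features["fixed"].shape[1],
                          features["seq_shifts"].shape[1])
        trained = train(net, features, y, spec)
        probs = predict(trained, features)
        assert probs.shape == (50, 4)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        # batched and per-instance predictions agree (order preserved)
        one = predict_on(net, take(features, np.array([7])))
        assert np.allclose(one[0], probs[7])

    def test_memorizing_model_argmax_is_true_class(self):
        features, y = toy_dataset(n=60, m=4)
        spec = ModelSpec(architecture="cnn", output_classes=4, epochs=120,
                         batch_size=8, seed=0)
        net = build_model(spec, features["fixed"].shape[1],
                          features["seq_shifts"].shape[1])
        trained = train(net, features, y, spec)
        assert (predict(trained, features).argmax(axis=1) == y).all()


class TestSplitsAndGrid:
    def test_split_disjoint_and_sized(self):
        features, y = toy_dataset(n=100, m=4)
        tr_f, tr_y, te_f, te_y = split_train_test(features, y, 0.2, 0)
        assert len(tr_y) == 80 and len(te_y) == 20

    def test_single_point_grid_returns_it(self):
        features, y = toy_dataset(n=60, m=3)
        protocol = TrainingProtocol(grids={"batch_size": [16]}, seed=0)

        def builder(batch_size):
            return ModelSpec(architecture="cnn", output_classes=3,
                             epochs=3, batch_size=batch_size, seed=0)

        best, table = grid_search(protocol, builder, features, y)
        assert best == {"batch_size": 16}
        assert len(table) == 1 and not table["failed"].any()

    def test_best_score_dominates_and_planted_epochs_recovered(self):
        # one epoch cannot fit the data; sixty can — the grid must find it
        features, y = toy_dataset(n=90, m=3)
        protocol = TrainingProtocol(grids={"epochs": [1, 60]}, seed=0)

        def builder(epochs):
            return ModelSpec(architecture="cnn", output_classes=3,
                             epochs=epochs, batch_size=8, seed=0)

        best, table = grid_search(protocol, builder, features, y)
        assert best == {"epochs": 60}
        ok = table[~table["failed"]]
        assert ok["mean_val_accuracy"].max() == ok.loc[
            ok["epochs"] == 60, "mean_val_accuracy"
        ].iloc[0]

    def test_momentum_grid_has_six_points(self):
        assert len(TrainingProtocol.MOMENTUM_GRID) == 6
        assert TrainingProtocol.MOMENTUM_GRID == (0.0, 0.2, 0.4, 0.6,
                                                  0.8, 1.0)


class TestPersistence:
    def test_save_load_same_predictions(self, tmp_path):
        features, y = toy_dataset(n=40, m=3)
        spec = ModelSpec(architecture="cnn", output_classes=3, epochs=4,
                         seed=0)
        net = build_model(spec, features["fixed"].shape[1],
                          features["seq_shifts"].shape[1])
        trained = train(net, features, y, spec)
        trained.save(tmp_path / "model")
        again = load_model(tmp_path / "model", features["fixed"].shape[1],
                           features["seq_shifts"].shape[1])
        assert np.allclose(predict(again, features),
                           predict(trained, features))
        assert (tmp_path / "model" / "history.csv").exists()
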