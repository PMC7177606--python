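"""Activations, loss, normalization, splitting, and network training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from saruq.benchmarks import ols_floor, svd_reconstruction_floor
from saruq.nets import (
    MLP,
    AutoencoderModel,
    MinMaxNormalizer,
    NetworkSpec,
    linear_activation,
    load_checkpoint,
    mse,
    relu,
    save_checkpoint,
    split_train_val,
    train_autoencoder,
    train_surrogate,
)


class TestActivations:
    @pytest.mark.parametrize("a, expected", [(-1.0, 0.0), (2.0, 2.0), (0.0, 0.0)])
    def test_relu_cases(self, a, expected):
        assert relu(a) == expected

    def test_relu_idempotent_and_nonnegative(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        np.testing.assert_array_equal(relu(relu(x)), relu(x))
        assert np.all(relu(x) >= 0)

    @pytest.mark.parametrize("a", [3.5, -2.0, 0.0])
    def test_linear_is_identity(self, a):
        assert linear_activation(a) == a


class TestMse:
    def test_identical_vectors_give_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    @pytest.mark.parametrize(
        "y, yhat, expected",
        [(([0.0, 0.0]), ([1.0, 1.0]), 1.0), (([1, 2, 3]), ([1, 2, 4]), 1 / 3)],
    )
    def test_hand_computed_values(self, y, yhat, expected):
        assert mse(y, yhat) == pytest.approx(expected, rel=1e-14)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mse(a, b) == pytest.approx(mse(b, a), rel=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse([1.0], [1.0, 2.0])


class TestNormalizer:
    def test_column_endpoints_map_to_unit_interval(self):
        norm = MinMaxNormalizer().fit(np.array([[2.0], [4.0]]))
        np.testing.assert_allclose(
            norm.transform(np.array([[2.0], [4.0]])), [[0.0], [1.0]]
        )

    @settings(deadline=None, max_examples=30)
    @given(
        arrays(np.float64, (5, 4), elements=st.floats(-1e3, 1e3, allow_nan=False))
    )
    def test_roundtrip_exact(self, X):
        for mode in ("per_column", "global"):
            norm = MinMaxNormalizer(mode=mode).fit(X)
            np.testing.assert_allclose(
                norm.inverse_transform(norm.transform(X)), X, atol=1e-12
            )

    def test_constant_column_convention(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        norm = MinMaxNormalizer().fit(X)
        out = norm.transform(X)
        np.testing.assert_array_equal(out[:, 0], 0.0)
        np.testing.assert_allclose(norm.inverse_transform(out)[:, 0], 5.0)

    def test_unfitted_state_rejected(self):
        with pytest.raises(RuntimeError, match="fitted"):
            MinMaxNormalizer().transform(np.zeros((2, 2)))

    def test_state_dict_roundtrip(self):
        X = np.random.default_rng(3).random((4, 3))
        norm = MinMaxNormalizer(mode="global").fit(X)
        back = MinMaxNormalizer.from_state(norm.state_dict())
        np.testing.assert_allclose(back.transform(X), norm.transform(X))


class TestSplit:
    @pytest.mark.parametrize("n, frac, n_val", [(200, 0.30, 60), (100, 0.30, 30)])
    def test_thirty_percent_rule(self, n, frac, n_val):
        train, val = split_train_val(n, frac, seed=0)
        assert len(val) == n_val
        assert len(train) == n - n_val

    def test_disjoint_exhaustive_reproducible(self):
        t1, v1 = split_train_val(50, 0.2, seed=7)
        t2, v2 = split_train_val(50, 0.2, seed=7)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(v1, v2)
        assert set(t1) | set(v1) == set(range(50))
        assert set(t1) & set(v1) == set()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(1, 0.3, seed=0)
        with pytest.raises(ValueError):
            split_train_val(10, 1.5, seed=0)


def _low_rank_data(n, D, rank, seed, fluctuation=0.05, decay=0.6):
    """Exact rank-`rank` non-negative data with few-percent variability and a
    decaying mode spectrum (the regime smooth field ensembles live in)."""
    rng = np.random.default_rng(seed)
    B = rng.random((rank, D))
    C = 1 + fluctuation * rng.uniform(-1, 1, size=(n, rank)) * decay ** np.arange(rank)
    return C @ B / rank


class TestAutoencoder:
    def test_asymmetric_spec_rejected(self):
        spec = NetworkSpec(hidden_widths=(8, 4, 6), epochs=1, batch_size=2)
        with pytest.raises(ValueError, match="symmetric"):
            train_autoencoder(np.random.default_rng(0).random((10, 12)), spec)

    def test_wide_bottleneck_rejected(self):
        spec = NetworkSpec(hidden_widths=(8, 20, 8), epochs=1, batch_size=2)
        with pytest.raises(ValueError, match="bottleneck"):
            train_autoencoder(np.random.default_rng(0).random((10, 12)), spec)

    def test_reaches_svd_floor_on_low_rank_data(self):
        """Held-out reconstruction approaches the truncated-SVD bound."""
        X = _low_rank_data(300, 60, 3, seed=5)
        norm = MinMaxNormalizer(mode="global").fit(X[:200])
        xtr, xte = norm.transform(X[:200]), norm.transform(X[200:])
        spec = NetworkSpec(
            hidden_widths=(30, 5, 30), epochs=2000, batch_size=20,
            learning_rate=2e-3, seed=1, activation_margin=6.0,
        )
        model, report = train_autoencoder(xtr, spec)
        test_mse = mse(xte, model.reconstruct(xte))
        floor = svd_reconstruction_floor(xtr, xte, 5)
        assert test_mse <= floor + 1e-6
        assert report.train_mse < 1e-5

    def test_encode_decode_shapes_and_self_consistency(self):
        X = _low_rank_data(40, 30, 2, seed=8)
        spec = NetworkSpec(hidden_widths=(12, 4, 12), epochs=50, batch_size=10, seed=2)
        model, report = train_autoencoder(X, spec)
        codes = model.encode(X)
        assert codes.shape == (40, 4)
        assert model.decode(codes).shape == (40, 30)
        # reported MSEs must equal a post-hoc recomputation from the weights
        from saruq.nets import split_train_val as sv

        tr, va = sv(40, 0.3, spec.seed)
        assert report.train_mse == pytest.approx(
            mse(X[tr], model.reconstruct(X[tr])), abs=1e-10
        )
        assert report.validation_mse == pytest.approx(
            mse(X[va], model.reconstruct(X[va])), abs=1e-10
        )

    def test_loss_history_finite_and_recorded(self):
        X = _low_rank_data(30, 20, 2, seed=9)
        spec = NetworkSpec(hidden_widths=(8, 3, 8), epochs=25, batch_size=10, seed=3)
        _, report = train_autoencoder(X, spec)
        assert len(report.loss_history) == 25
        assert np.isfinite(report.loss_history).all()

    def test_dimension_mismatch_rejected(self):
        X = _low_rank_data(30, 20, 2, seed=10)
        spec = NetworkSpec(hidden_widths=(8, 3, 8), epochs=5, batch_size=10, seed=0)
        model, _ = train_autoencoder(X, spec)
        with pytest.raises(ValueError, match="dimension"):
            model.encode(np.zeros((2, 7)))
        with pytest.raises(ValueError, match="dimension"):
            model.decode(np.zeros((2, 7)))

    def test_zero_weight_decoder_outputs_bias(self):
        mlp = MLP([4, 3, 4], seed=0)
        for W in mlp.W:
            W[:] = 0
        mlp.b[-1][:] = 7.5
        model = AutoencoderModel(mlp=mlp, code_layer=1)
        np.testing.assert_allclose(model.decode(np.ones((2, 3))), 7.5)


class TestSurrogate:
    def test_reaches_ols_floor_on_affine_codes(self):
        rng = np.random.default_rng(4)
        Z = rng.integers(1, 10, size=(120, 4))
        z = (Z - 1) / 8.0
        A = rng.normal(size=(4, 3)) * 0.05
        codes = z @ A + 0.5
        spec = NetworkSpec(
            hidden_widths=(16, 8), epochs=2000, batch_size=20,
            learning_rate=2e-3, seed=5, activation_margin=6.0,
        )
        model, report = train_surrogate(z[:80], codes[:80], spec)
        test_mse = mse(codes[80:], model.predict_codes(z[80:]))
        floor = ols_floor(z[:80], codes[:80], z[80:], codes[80:])
        assert test_mse <= floor + 1e-6

    def test_constant_codes_learned_exactly(self):
        rng = np.random.default_rng(6)
        z = rng.random((40, 3))
        codes = np.full((40, 2), 0.37)
        spec = NetworkSpec(hidden_widths=(8, 4), epochs=300, batch_size=10, seed=7)
        model, report = train_surrogate(z, codes, spec)
        assert report.train_mse < 1e-8
        assert mse(codes, model.predict_codes(z)) < 1e-8

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            train_surrogate(
                np.zeros((5, 2)), np.zeros((6, 2)),
                NetworkSpec(hidden_widths=(4,), epochs=1, batch_size=2),
            )

    def test_batch_larger_than_samples_rejected(self):
        with pytest.raises(ValueError, match="batch_size"):
            train_surrogate(
                np.zeros((5, 2)), np.zeros((5, 2)),
                NetworkSpec(hidden_widths=(4,), epochs=1, batch_size=50),
            )


class TestCheckpoints:
    def test_autoencoder_roundtrip(self, tmp_path):
        X = _low_rank_data(30, 20, 2, seed=11)
        spec = NetworkSpec(hidden_widths=(8, 3, 8), epochs=20, batch_size=10, seed=1)
        model, _ = train_autoencoder(X, spec)
        model.normalizer = MinMaxNormalizer(mode="global").fit(X)
        save_checkpoint(model, spec, tmp_path / "ae.npz")
        back, back_spec = load_checkpoint(tmp_path / "ae.npz")
        np.testing.assert_array_equal(back.reconstruct(X), model.reconstruct(X))
        assert back.code_dim == 3
        assert back_spec == spec
        assert back.normalizer is not None

    def test_regressor_roundtrip(self, tmp_path):
        rng = np.random.default_rng(12)
        z, codes = rng.random((30, 4)), rng.random((30, 3))
        spec = NetworkSpec(hidden_widths=(8,), epochs=10, batch_size=10, seed=2)
        model, _ = train_surrogate(z, codes, spec)
        save_checkpoint(model, spec, tmp_path / "reg.npz")
        back, _ = load_checkpoint(tmp_path / "reg.npz")
        np.testing.assert_array_equal(back.predict_codes(z), model.predict_codes(z))
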