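"""Ensemble statistics, surrogate prediction, and the end-to-end pipeline."""

import dataclasses

import numpy as np
import pytest

from saruq.doe import Configuration, enumerate_configurations, sample_configurations
from saruq.fixtures import tiny_pipeline_config
from saruq.forward import ForwardModelParams, generate_field
from saruq.nets import MLP, AutoencoderModel, MinMaxNormalizer, mse
from saruq.uq import (
    SurrogatePair,
    ensemble_statistics,
    evaluate_surrogate,
    normalize_indices,
    predict_sar,
    run_uq,
)


class TestEnsembleStatistics:
    def test_identical_fields_have_zero_spread(self):
        fields = np.tile([1.0, 0.0, 2.0], (5, 1))
        s = ensemble_statistics(fields)
        np.testing.assert_array_equal(s.std, 0.0)
        assert s.cv_ratio[0] == 0.0 and s.cv_ratio[2] == 0.0
        assert np.isnan(s.cv_ratio[1])  # zero mean is masked

    def test_two_member_hand_computation(self):
        """Values 1 and 3: mean 2, sample std sqrt(2), ratio 70.71%."""
        s = ensemble_statistics(np.array([[1.0], [3.0]]))
        assert s.mean[0] == pytest.approx(2.0)
        assert s.std[0] == pytest.approx(np.sqrt(2.0), rel=1e-12)
        assert s.cv_ratio[0] == pytest.approx(70.7107, abs=1e-3)

    def test_single_field_rejected(self):
        with pytest.raises(ValueError, match="2 fields"):
            ensemble_statistics(np.ones((1, 4)))

    def test_matches_one_pass_reference(self):
        """Two-pass numpy statistics agree with a streaming implementation."""
        rng = np.random.default_rng(3)
        fields = rng.random((40, 17))
        s = ensemble_statistics(fields)
        n = 0
        acc = np.zeros(17)
        acc2 = np.zeros(17)
        for row in fields:  # Welford-style one-pass
            n += 1
            d = row - acc
            acc += d / n
            acc2 += d * (row - acc)
        np.testing.assert_allclose(s.mean, acc, atol=1e-10)
        np.testing.assert_allclose(s.std, np.sqrt(acc2 / (n - 1)), atol=1e-10)

    def test_exhaustive_enumeration_oracle(self, two_electrode_layout, tissue, tiny_grid):
        """Statistics over all 81 two-electrode configurations equal the
        brute-force moments of the same fields."""
        combos = enumerate_configurations(2)
        assert len(combos) == 81
        params = ForwardModelParams()
        fields = np.stack(
            [
                generate_field(two_electrode_layout, Configuration(c), tissue,
                               tiny_grid, params, seed=4).values
                for c in combos
            ]
        )
        s = ensemble_statistics(fields)
        np.testing.assert_allclose(s.mean, fields.sum(0) / 81, rtol=1e-14)
        expected_var = ((fields - fields.mean(0)) ** 2).sum(0) / 80
        np.testing.assert_allclose(s.std, np.sqrt(expected_var), rtol=1e-12)

    def test_no_spurious_uncertainty_without_bumps(
        self, two_electrode_layout, tissue, tiny_grid
    ):
        """bump_amplitude=0 means configuration changes nothing: cv == 0."""
        params = ForwardModelParams(bump_amplitude=0.0)
        configs = sample_configurations(2, 20, seed=6)
        fields = np.stack(
            [
                generate_field(two_electrode_layout, Configuration(c), tissue,
                               tiny_grid, params, seed=4).values
                for c in configs
            ]
        )
        s = ensemble_statistics(fields)
        assert np.nanmax(np.abs(s.cv_ratio)) <= 1e-8


def _identity_autoencoder(D):
    mlp = MLP([D, D, D], seed=0, bias_init=0.0)
    for i, W in enumerate(mlp.W):
        W[:] = np.eye(D)
    return AutoencoderModel(mlp=mlp, code_layer=1)


class TestPrediction:
    def test_normalize_indices_range(self):
        z = normalize_indices(np.array([[1, 5, 9]]))
        np.testing.assert_allclose(z, [[0.0, 0.5, 1.0]])
        with pytest.raises(ValueError):
            normalize_indices(np.array([[0]]))

    def test_identity_decoder_passes_codes_through(self):
        """With an identity autoencoder the prediction equals the codes the
        regressor produces (degenerate composition check)."""
        ae = _identity_autoencoder(4)
        codes = np.array([[0.1, 0.2, 0.3, 0.4]])
        np.testing.assert_allclose(ae.decode(codes), codes)
        np.testing.assert_allclose(ae.encode(codes), codes)

    def test_prediction_deterministic(self):
        cfg = tiny_pipeline_config(seed=1)
        cfg = dataclasses.replace(
            cfg,
            ae_spec=dataclasses.replace(cfg.ae_spec, epochs=40),
            reg_spec=dataclasses.replace(cfg.reg_spec, epochs=40),
            n_ensemble=10,
        )
        res = run_uq(cfg)
        c = Configuration(np.array([4, 7]))
        p1 = predict_sar(c, res.pair.regressor, res.pair.autoencoder)
        p2 = predict_sar(c, res.pair.regressor, res.pair.autoencoder)
        np.testing.assert_array_equal(p1, p2)
        assert np.all(p1 >= 0)


@pytest.fixture(scope="module")
def tiny_result():
    return run_uq(tiny_pipeline_config(seed=3))


class TestPipeline:

    def test_completes_with_consistent_shapes(self, tiny_result):
        s = tiny_result.surrogate_summary
        assert s.mean.shape == (125,)
        assert s.n_ensemble == 150
        assert np.all(s.std >= 0)
        assert tiny_result.ae_report.test_mse is not None

    def test_summary_masks_outside_brain(self, tiny_result):
        s = tiny_result.surrogate_summary
        cfg = tiny_pipeline_config(seed=3)
        outside = cfg.grid.radii() > 68.0
        assert np.all(np.isnan(s.cv_ratio[outside]))
        assert np.all(~np.isnan(s.cv_ratio[~outside]))

    def test_normalized_and_physical_summaries_emitted(self, tiny_result):
        assert tiny_result.surrogate_summary.normalized is False
        assert tiny_result.surrogate_summary_normalized.normalized is True

    def test_reported_test_mse_is_self_consistent(self, tiny_result):
        m = tiny_result.test_metrics
        assert m["autoencoder_test_mse"] >= 0
        assert tiny_result.reg_report.test_mse == pytest.approx(
            m["code_test_mse"], abs=1e-12
        )

    def test_manifest_reproducibility(self, tiny_result):
        """Re-running the identical configuration reproduces all hashes."""
        res2 = run_uq(tiny_pipeline_config(seed=3))
        for key in ("dataset_hash", "mc_configs_hash", "summary_mean_hash", "summary_std_hash"):
            assert res2.manifest[key] == tiny_result.manifest[key]

    def test_mc_mean_stabilises_with_ensemble_growth(self, tiny_result):
        """Nested Monte-Carlo ensembles: halving the ensemble moves voxel
        means by no more than a few standard errors."""
        cfg = tiny_pipeline_config(seed=3)
        configs = sample_configurations(2, 150, seed=cfg.seed + 3)
        small = tiny_result.pair.predict(configs[:75])
        big = tiny_result.pair.predict(configs)
        s_small = ensemble_statistics(small)
        s_big = ensemble_statistics(big)
        se = s_big.std / np.sqrt(75)
        active = s_big.mean > 0
        assert np.all(
            np.abs(s_small.mean[active] - s_big.mean[active]) <= 6 * se[active] + 1e-12
        )

    def test_stage_failure_names_stage(self):
        cfg = tiny_pipeline_config(seed=3)
        bad = dataclasses.replace(
            cfg, ae_spec=dataclasses.replace(cfg.ae_spec, batch_size=10_000)
        )
        with pytest.raises(RuntimeError, match="train_autoencoder"):
            run_uq(bad)


class TestEvaluateSurrogate:
    def test_train_test_overlap_rejected(self):
        ae = _identity_autoencoder(3)
        mlp = MLP([2, 3], seed=0)
        from saruq.nets import SurrogateRegressor

        pair = SurrogatePair(
            regressor=SurrogateRegressor(mlp=mlp), autoencoder=ae,
            sar_normalizer=MinMaxNormalizer(),
        )
        configs = np.array([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="overlap"):
            evaluate_surrogate(pair, configs, np.zeros((2, 3)), train_configs=configs)

    def test_reported_equals_external_recomputation(self):
        """evaluate_surrogate's numbers match mse() applied to saved outputs."""
        cfg = tiny_pipeline_config(seed=2)
        cfg = dataclasses.replace(
            cfg,
            ae_spec=dataclasses.replace(cfg.ae_spec, epochs=60),
            reg_spec=dataclasses.replace(cfg.reg_spec, epochs=60),
            n_ensemble=10,
        )
        res = run_uq(cfg)
        from saruq.forward import build_dataset

        ds = build_dataset(cfg.layout, cfg.tissue, cfg.grid, cfg.forward_params, 12, seed=99)
        xn = res.pair.sar_normalizer.transform(ds.fields)
        metrics = evaluate_surrogate(res.pair, ds.configs, xn)
        codes = res.pair.autoencoder.encode(xn)
        assert metrics["autoencoder_test_mse"] == pytest.approx(
            mse(xn, res.pair.autoencoder.decode(codes)), abs=1e-12
        )
        pred = res.pair.autoencoder.decode(
            res.pair.regressor.predict_codes(normalize_indices(ds.configs))
        )
        assert metrics["end_to_end_test_mse"] == pytest.approx(mse(xn, pred), abs=1e-12)
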