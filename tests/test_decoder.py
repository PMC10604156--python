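"""Decoder family: loss algebra, architecture, training, renormalization,
and the ridge baseline, checked against independent oracles."""

import numpy as np
import pytest
from scipy.special import erf

from brainrecon import _mlp
from brainrecon.data_model import FeatureMatrix, ValidationError, VoxelMatrix
from brainrecon.decoder import (
    BrainMlpSpec,
    DegenerateCosineError,
    FeatureStats,
    TrainConfig,
    build_brainmlp,
    combined_loss,
    fit_ridge,
    load_decoder,
    predict_features,
    renormalize,
    save_decoder,
    train_decoder,
)


def _vm(values):
    values = np.asarray(values, float)
    return VoxelMatrix(
        values, [f"s{i}" for i in range(values.shape[0])], [f"v{j}" for j in range(values.shape[1])]
    )


class TestCombinedLoss:
    def test_perfect_prediction_reduces_to_cosine_weight(self, rng):
        for _ in range(20):
            z = rng.normal(size=(6, 9))
            assert combined_loss(z, z) == pytest.approx(-0.1, abs=1e-12)

    def test_orthogonal_hand_case(self):
        # one sample, z=(1,0), zhat=(0,1): 0.9*2 + (-0.1)*0 = 1.8
        assert combined_loss([[1.0, 0.0]], [[0.0, 1.0]]) == pytest.approx(1.8, abs=1e-15)

    def test_antiparallel_sign_algebra(self, rng):
        z = rng.normal(size=(5, 7))
        expected = 0.9 * (np.sum((2 * z) ** 2, axis=1)).mean() + 0.1
        assert combined_loss(z, -z) == pytest.approx(expected, rel=1e-12)

    def test_lower_bound(self, rng):
        for _ in range(20):
            z, zh = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
            assert combined_loss(z, zh) >= -0.1

    def test_zero_norm_sample_rejected(self):
        with pytest.raises(DegenerateCosineError):
            combined_loss([[0.0, 0.0]], [[1.0, 0.0]])


def _manual_forward(params, x, n_blocks, eps=1e-5):
    """Independent re-implementation of the eval-mode forward pass."""

    def gelu(v):
        return 0.5 * v * (1 + erf(v / np.sqrt(2)))

    h = gelu(x @ params["in.W"] + params["in.b"])
    for k in range(n_blocks):
        a = h @ params[f"blk{k}.W"] + params[f"blk{k}.b"]
        mu, var = a.mean(axis=1, keepdims=True), a.var(axis=1, keepdims=True)
        ln = params[f"blk{k}.g"] * (a - mu) / np.sqrt(var + eps) + params[f"blk{k}.beta"]
        h = gelu(ln) + h
    return h @ params["head.W"] + params["head.b"]


class TestBrainMlpArchitecture:
    def test_parameter_count_from_layer_algebra(self):
        # input proj (10*8+8) + block [(8*8+8) + LayerNorm 2*8] + head (8*4+4)
        spec = BrainMlpSpec(in_dim=10, out_dim=4, n_blocks=1, hidden_dim=8)
        assert spec.n_parameters == 88 + (72 + 16) + 36 == 212
        dec = build_brainmlp(spec, seed=0)
        assert sum(v.size for v in dec.parameters.values()) == 212

    def test_seeded_init_reproducible(self):
        spec = BrainMlpSpec(6, 3, n_blocks=2, hidden_dim=5)
        a, b = build_brainmlp(spec, seed=4), build_brainmlp(spec, seed=4)
        for k in a.parameters:
            assert np.array_equal(a.parameters[k], b.parameters[k])

    def test_forward_matches_manual_oracle(self, rng):
        spec = BrainMlpSpec(7, 3, n_blocks=2, hidden_dim=5, dropout_rate=0.0)
        dec = build_brainmlp(spec, seed=1)
        x = rng.normal(size=(4, 7))
        out, _ = _mlp.forward(dec.parameters, x, spec.n_blocks, 0.0, spec.layernorm_eps)
        assert np.allclose(out, _manual_forward(dec.parameters, x, 2), atol=1e-12)

    def test_zero_dropout_forward_same_in_train_and_eval(self, rng):
        spec = BrainMlpSpec(5, 2, n_blocks=1, hidden_dim=4, dropout_rate=0.0)
        dec = build_brainmlp(spec, seed=2)
        x = rng.normal(size=(3, 5))
        eval_out, _ = _mlp.forward(dec.parameters, x, 1, 0.0, 1e-5, rng=None)
        train_out, _ = _mlp.forward(
            dec.parameters, x, 1, 0.0, 1e-5, rng=np.random.Generator(np.random.PCG64(0))
        )
        assert np.array_equal(eval_out, train_out)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            BrainMlpSpec(in_dim=0, out_dim=2)
        with pytest.raises(ValidationError):
            BrainMlpSpec(in_dim=2, out_dim=2, dropout_rate=1.0)


class TestBackpropagation:
    def test_gradients_match_finite_differences(self, rng):
        spec = BrainMlpSpec(3, 2, n_blocks=1, hidden_dim=4, dropout_rate=0.0)
        dec = build_brainmlp(spec, seed=3)
        params = dec.parameters
        x = rng.normal(size=(2, 3))
        z = rng.normal(size=(2, 2))

        def loss_of(p):
            out, _ = _mlp.forward(p, x, 1, 0.0, 1e-5)
            return combined_loss(z, out)

        out, cache = _mlp.forward(params, x, 1, 0.0, 1e-5)
        from brainrecon.decoder import _loss_and_grad

        _, dpred = _loss_and_grad(z, out, 0.9, -0.1)
        grads = _mlp.backward(params, cache, dpred, 1)

        h = 1e-6
        for key in params:
            g_num = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = params[key][idx]
                params[key][idx] = orig + h
                up = loss_of(params)
                params[key][idx] = orig - h
                down = loss_of(params)
                params[key][idx] = orig
                g_num[idx] = (up - down) / (2 * h)
            assert np.allclose(grads[key], g_num, atol=1e-6), key


class TestTraining:
    @staticmethod
    def _linear_problem(rng, n=60, p=12, d=4):
        w = rng.normal(size=(p, d))
        x = rng.normal(size=(n, p))
        return _vm(x), FeatureMatrix(x @ w, "latent")

    def test_loss_descends_on_realizable_target(self, rng):
        x, z = self._linear_problem(rng)
        spec = BrainMlpSpec(12, 4, n_blocks=1, hidden_dim=16, dropout_rate=0.0)
        dec = train_decoder(x, z, spec, TrainConfig(lr_init=1e-3, epochs=30, seed=0))
        assert dec.history[-1] < dec.history[0]
        assert len(dec.history) == 30

    def test_seeded_training_bit_reproducible(self, rng):
        x, z = self._linear_problem(rng)
        spec = BrainMlpSpec(12, 4, n_blocks=1, hidden_dim=8, dropout_rate=0.2)
        cfg = TrainConfig(lr_init=1e-3, epochs=5, seed=9)
        a = train_decoder(x, z, spec, cfg)
        b = train_decoder(x, z, spec, cfg)
        assert a.history == b.history
        for k in a.parameters:
            assert np.array_equal(a.parameters[k], b.parameters[k])

    def test_prediction_deterministic_and_dropout_off(self, rng):
        x, z = self._linear_problem(rng)
        spec = BrainMlpSpec(12, 4, n_blocks=1, hidden_dim=8, dropout_rate=0.5)
        dec = train_decoder(x, z, spec, TrainConfig(lr_init=1e-3, epochs=3, seed=0))
        p1, p2 = predict_features(dec, x), predict_features(dec, x)
        assert np.array_equal(p1.values, p2.values)

    def test_untrained_decoder_zero_input_is_bias_propagation(self):
        spec = BrainMlpSpec(6, 3, n_blocks=1, hidden_dim=4, dropout_rate=0.0)
        dec = build_brainmlp(spec, seed=5)
        zeros = _vm(np.zeros((2, 6)))
        out = predict_features(dec, zeros)
        expected = _manual_forward(dec.parameters, np.zeros((2, 6)), 1)
        assert np.allclose(out.values, expected, atol=1e-12)
        assert np.array_equal(out.values[0], out.values[1])

    def test_dimension_mismatch_rejected(self, rng):
        x, z = self._linear_problem(rng)
        dec = train_decoder(
            x, z, BrainMlpSpec(12, 4, n_blocks=1, hidden_dim=8), TrainConfig(epochs=2)
        )
        with pytest.raises(ValidationError, match="voxels"):
            predict_features(dec, _vm(np.zeros((1, 5))))

    def test_noiseless_recovery_per_dimension(self):
        # enough samples and weight decay for the net to generalize the
        # exactly-linear noiseless forward map
        from brainrecon.data_model import average_repeats
        from brainrecon.synthetic import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_train=480, n_classes_train=60, images_per_class=8, n_test=30,
            n_test_repeats=2, n_voxels=100, latent_dim=16, visual_dim=24,
            text_dim=8, snr=np.inf, seed=1, image_size=32,
        )
        train, test, truth = generate_dataset(cfg)
        z = truth.true_latents["train"]
        spec = BrainMlpSpec(cfg.n_voxels, z.n_dims, n_blocks=1, hidden_dim=128, dropout_rate=0.0)
        dec = train_decoder(
            train.fmri, z, spec,
            TrainConfig(lr_init=1e-2, epochs=600, seed=0, weight_decay=0.1),
        )
        pred = predict_features(dec, average_repeats(test.fmri)).values
        zt = truth.true_latents["test"].values
        rs = [np.corrcoef(pred[:, j], zt[:, j])[0, 1] for j in range(zt.shape[1])]
        assert min(rs) > 0.95


class TestRenormalize:
    def test_hand_evaluation(self):
        pred = FeatureMatrix(np.array([[0.0], [2.0]]))
        out = renormalize(pred, FeatureStats(np.array([10.0]), np.array([1.0])))
        assert np.allclose(out.values, [[9.0], [11.0]])

    def test_output_stats_match_target_exactly(self, rng):
        pred = FeatureMatrix(rng.normal(2.0, 3.0, size=(40, 6)))
        stats = FeatureStats(rng.normal(size=6), rng.random(6) + 0.5)
        out = renormalize(pred, stats)
        assert np.allclose(out.values.mean(axis=0), stats.mean, atol=1e-8)
        assert np.allclose(out.values.std(axis=0), stats.std, atol=1e-8)

    def test_fixed_point_and_idempotence(self, rng):
        stats = FeatureStats(np.array([1.0, -2.0]), np.array([0.5, 2.0]))
        base = rng.normal(size=(30, 2))
        base = (base - base.mean(axis=0)) / base.std(axis=0) * stats.std + stats.mean
        pred = FeatureMatrix(base)
        once = renormalize(pred, stats)
        assert np.allclose(once.values, base, atol=1e-12)
        twice = renormalize(once, stats)
        assert np.allclose(twice.values, once.values, atol=1e-12)

    def test_zero_variance_dim_falls_back_to_mean(self, rng, caplog):
        vals = rng.normal(size=(10, 2))
        vals[:, 1] = 7.0
        stats = FeatureStats(np.array([0.0, 5.0]), np.array([1.0, 2.0]))
        with caplog.at_level("WARNING"):
            out = renormalize(FeatureMatrix(vals), stats)
        assert np.allclose(out.values[:, 1], 5.0)
        assert any("zero-variance" in r.message for r in caplog.records)


class TestRidge:
    def test_exact_line_through_origin(self):
        x = _vm([[1.0], [2.0]])
        z = FeatureMatrix([[2.0], [4.0]])
        dec = fit_ridge(x, z, l2=0.0, standardize_voxels=False)
        assert dec.parameters["coef"][0, 0] == pytest.approx(2.0, abs=1e-10)
        assert dec.parameters["intercept"][0] == pytest.approx(0.0, abs=1e-10)

    def test_infinite_shrinkage_predicts_training_mean(self, rng):
        x = _vm(rng.normal(size=(20, 5)))
        z = FeatureMatrix(rng.normal(3.0, 1.0, size=(20, 2)))
        dec = fit_ridge(x, z, l2=1e12)
        pred = predict_features(dec, x)
        assert np.allclose(pred.values, z.values.mean(axis=0), atol=1e-6)

    def test_noiseless_closed_form_recovery(self, rng):
        w = rng.normal(size=(10, 3))
        x = rng.normal(size=(50, 10))
        dec = fit_ridge(_vm(x), FeatureMatrix(x @ w), l2=1e-12)
        x_new = rng.normal(size=(20, 10))
        pred = predict_features(dec, _vm(x_new)).values
        for j in range(3):
            assert np.corrcoef(pred[:, j], (x_new @ w)[:, j])[0, 1] > 0.999

    def test_singular_system_without_penalty_rejected(self, rng):
        x = _vm(rng.normal(size=(3, 10)))  # fewer samples than voxels
        z = FeatureMatrix(rng.normal(size=(3, 2)))
        with pytest.raises(np.linalg.LinAlgError, match="l2 > 0"):
            fit_ridge(x, z, l2=0.0)


class TestCheckpointSerialization:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        x = _vm(rng.normal(size=(30, 8)))
        z = FeatureMatrix(rng.normal(size=(30, 3)), "visual")
        spec = BrainMlpSpec(8, 3, n_blocks=1, hidden_dim=6)
        dec = train_decoder(x, z, spec, TrainConfig(epochs=3, seed=1))
        save_decoder(dec, tmp_path / "ck.npz")
        back = load_decoder(tmp_path / "ck.npz")
        assert back.history == dec.history
        assert np.array_equal(
            predict_features(back, x).values, predict_features(dec, x).values
        )
        assert np.allclose(back.train_pred_stats.mean, dec.train_pred_stats.mean)

    def test_ridge_round_trip(self, rng, tmp_path):
        x = _vm(rng.normal(size=(20, 6)))
        z = FeatureMatrix(rng.normal(size=(20, 2)))
        dec = fit_ridge(x, z, l2=1.0)
        save_decoder(dec, tmp_path / "r.npz")
        back = load_decoder(tmp_path / "r.npz")
        assert np.array_equal(
            predict_features(back, x).values, predict_features(dec, x).values
        )
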