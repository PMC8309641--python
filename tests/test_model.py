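"""The CNN and its attention block: oracles, gradients, training behaviour."""

from dataclasses import replace

import numpy as np
import pytest

from mieeg import CbamCnn, ModelConfig
from mieeg import nn
from mieeg.model import encode_labels, train

from oracles import cbam_loops, channel_attention_loops, spatial_attention_loops


def _tiny_cbam_params(c=3, r=1, k=7, seed=0):
    rng_for = lambda name: np.random.default_rng([seed, abs(hash(name)) % 2**31])
    return nn.init_cbam_params(c, r, k, rng_for)


class TestRelu:
    @pytest.mark.parametrize("x,expected", [(3.0, 3.0), (-2.0, 0.0), (0.0, 0.0)])
    def test_values(self, x, expected):
        assert nn.relu(x) == expected

    @pytest.mark.parametrize("x,expected", [(3.0, 1.0), (-2.0, 0.0), (0.0, 0.0)])
    def test_subgradient(self, x, expected):
        assert nn.relu_grad(np.array(x)) == expected


class TestAttentionOracles:
    @pytest.mark.parametrize("shape", [(2, 2, 2), (3, 4, 4)])
    def test_channel_attention_matches_loop_reference(self, shape, rng):
        c = shape[0]
        params = _tiny_cbam_params(c=c, r=1)
        f = rng.standard_normal(shape)
        gate = nn.channel_attention(f, {k.replace("ca_", ""): v for k, v in
                                        params.items() if k.startswith("ca_")})
        ref = channel_attention_loops(
            f, params["ca_W0"], params["ca_b0"], params["ca_W1"], params["ca_b1"]
        )
        assert gate.shape == (c, 1, 1)
        assert np.allclose(gate[:, 0, 0], ref, atol=1e-10)

    @pytest.mark.parametrize("shape", [(1, 3, 3), (3, 4, 4)])
    def test_spatial_attention_matches_loop_reference(self, shape, rng):
        params = _tiny_cbam_params(c=shape[0], r=1, k=7)
        f = rng.standard_normal(shape)
        gate = nn.spatial_attention(f, {k.replace("sa_", ""): v for k, v in
                                        params.items() if k.startswith("sa_")})
        ref = spatial_attention_loops(f, params["sa_W"], params["sa_b"])
        assert gate.shape == (1, *shape[1:])
        assert np.allclose(gate[0], ref, atol=1e-10)

    def test_cbam_matches_composed_loop_reference(self, rng):
        params = _tiny_cbam_params(c=3, r=1)
        f = rng.standard_normal((3, 4, 4))
        out = nn.cbam(f, params)
        assert out.shape == f.shape
        assert np.allclose(out, cbam_loops(f, params), atol=1e-10)

    def test_zero_parameters_give_exact_quarter_scaling(self, rng):
        params = {k: np.zeros_like(v) for k, v in _tiny_cbam_params(c=2).items()}
        f = rng.standard_normal((2, 4, 4))
        assert np.array_equal(nn.cbam(f, params), 0.25 * f)

    def test_attention_gates_strictly_inside_unit_interval(self, rng):
        params = _tiny_cbam_params(c=3, r=1, seed=4)
        f = 10.0 * rng.standard_normal((3, 6, 6))
        mc = nn.channel_attention(f, {k.replace("ca_", ""): v for k, v in
                                      params.items() if k.startswith("ca_")})
        ms = nn.spatial_attention(f, {k.replace("sa_", ""): v for k, v in
                                      params.items() if k.startswith("sa_")})
        for g in (mc, ms):
            assert np.all(g > 0) and np.all(g < 1)


class TestGradients:
    def test_network_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(
            input_size=8,
            conv_filters=(2, 3),
            cbam_reduction=2,
            dropout_rate=0.0,
            seed=3,
            dtype="float64",
        )
        m = CbamCnn(cfg)
        x = rng.standard_normal((4, 8, 8))
        y = np.array([0, 1, 0, 1])
        _, grads = m.loss_and_grads(x, y)
        eps = 1e-6
        for name, g in grads.items():
            p = m.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp, _ = m.loss_and_grads(x, y)
                p[idx] = old - eps
                lm, _ = m.loss_and_grads(x, y)
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-4 * max(1.0, abs(num)), name


class TestForward:
    def _model(self, **kw):
        return CbamCnn(
            ModelConfig(conv_filters=(2, 4), cbam_reduction=2, seed=1, **kw)
        )

    def test_probabilities_sum_to_one(self, rng):
        m = self._model()
        probs = m.predict_proba(rng.random((5, 64, 64)))
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self, rng):
        m = self._model()
        x = rng.random((64, 64))
        assert np.array_equal(m.forward(x), m.forward(x))

    def test_wrong_input_shape_rejected(self, rng):
        with pytest.raises(ValueError, match="64"):
            self._model().predict_proba(rng.random((5, 32, 32)))

    def test_cbam_preserves_shape_through_network(self, rng):
        with_att = self._model(use_cbam=True)
        without = self._model(use_cbam=False)
        x = rng.random((3, 64, 64))
        assert with_att.predict_proba(x).shape == without.predict_proba(x).shape

    def test_untrained_model_is_at_chance(self, rng):
        m = self._model()
        x = rng.random((200, 64, 64))
        y = np.tile([0, 1], 100)
        acc = (m.predict(x) == y).mean()
        assert 0.39 < acc < 0.61  # 3 sigma binomial band around 0.5


@pytest.fixture(scope="module")
def separable_data():
    """Images whose mean level encodes the class, plus pixel noise."""
    rng = np.random.default_rng(7)
    n = 60
    y = np.tile([0, 1], n // 2)
    shift = np.where(y == 0, -0.12, 0.12)[:, None, None]
    x = 0.5 + shift + 0.08 * rng.standard_normal((n, 64, 64))
    return np.clip(x, 0, 1), y


class TestTraining:
    def _config(self, **kw):
        base = dict(
            conv_filters=(2, 4),
            cbam_reduction=2,
            batch_size=4,
            max_epochs=12,
            seed=5,
        )
        base.update(kw)
        return ModelConfig(**base)

    def test_learns_separable_data(self, separable_data):
        x, y = separable_data
        m = train(x, y, self._config())
        losses = m.log_["loss"].to_numpy()
        assert losses[-1] < losses[0]
        assert (m.predict(x) == y).mean() > 0.9

    def test_seeded_training_is_reproducible(self, separable_data):
        x, y = separable_data
        cfg = self._config(max_epochs=3)
        a = train(x, y, cfg)
        b = train(x, y, cfg)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_zero_learning_rate_freezes_weights(self, separable_data):
        x, y = separable_data
        cfg = self._config(max_epochs=2, learning_rate=0.0)
        m = CbamCnn(cfg)
        before = {k: v.copy() for k, v in m.params.items()}
        m.fit(x, y)
        assert all(np.array_equal(before[k], m.params[k]) for k in before)

    def test_single_class_input_rejected(self, separable_data):
        x, _ = separable_data
        with pytest.raises(ValueError, match="both classes"):
            train(x[:10], np.zeros(10, dtype=int), self._config(max_epochs=1))

    def test_cbam_bypass_equals_plain_variant(self, separable_data):
        """Disabling attention reproduces the no-attention model exactly:
        shared layers draw from per-parameter streams."""
        x, y = separable_data
        cfg_on = self._config(max_epochs=2, use_cbam=True)
        cfg_off = self._config(max_epochs=2, use_cbam=False)
        a, b = CbamCnn(cfg_on), CbamCnn(cfg_off)
        for k in ("conv1_W", "conv2_W", "fc_W"):
            assert np.array_equal(a.params[k], b.params[k])
        a.config = replace(a.config, use_cbam=False)  # force-identity attention
        a.fit(x, y)
        b.fit(x, y)
        assert np.array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_save_load_round_trip(self, separable_data, tmp_path):
        x, y = separable_data
        m = train(x, y, self._config(max_epochs=1))
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = CbamCnn.load(path)
        assert np.array_equal(m.predict_proba(x[:5]), m2.predict_proba(x[:5]))

    def test_early_stopping_restores_best_weights(self, separable_data):
        x, y = separable_data
        cfg = self._config(max_epochs=30, validation_fraction=0.2, patience=3)
        m = train(x, y, cfg)
        assert "val_loss" in m.log_.columns
        assert len(m.log_) <= 30


class TestEncodeLabels:
    def test_strings_and_ints(self):
        assert np.array_equal(encode_labels(["left", "right", "left"]), [0, 1, 0])
        assert np.array_equal(encode_labels([1, 0]), [1, 0])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            encode_labels(["up"])


class TestModelConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"conv_filters": (0, 4)},
            {"dropout_rate": 1.0},
            {"cbam_reduction": 64, "conv_filters": (4, 8)},
            {"cbam_placement": "everywhere"},
            {"optimizer": "sgd"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)
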