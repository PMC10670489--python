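import dataclasses

import numpy as np
import pytest

from ramancell import deep
from ramancell.deep import hpo
from ramancell.spectra import Spectrum


def _tiny_cfg(**overrides):
    """Small but structurally complete network for component tests."""
    base = dict(
        n_layers=25, conv_filters=(2, 3, 4), n_points=96, lstm_units=10,
        dense_hidden=6, dropout=0.0, head_dropout=0.0, seed=0,
    )
    base.update(overrides)
    return deep.NetConfig(**base)


class TestWindowing:
    @pytest.mark.parametrize(
        "length, k_s, slice_len, dropped",
        [(1200, 3, 400, 0), (1201, 3, 400, 1), (100, 1, 100, 0), (10, 4, 2, 2)],
    )
    def test_slice_geometry(self, length, k_s, slice_len, dropped):
        values = np.arange(length, dtype=float)
        w = deep.window_spectrum(values, k_s)
        assert w.k_s == k_s
        assert all(s.size == slice_len for s in w.slices)
        assert w.concatenated().size == length - dropped
        assert np.array_equal(w.concatenated(), values[: length - dropped])

    def test_spectrum_input_keeps_source_id(self):
        s = Spectrum(np.arange(600.0, 612.0), np.arange(12.0), cell_id="T001")
        assert deep.window_spectrum(s, 3).source_id == "T001"

    def test_invalid_k_s(self):
        with pytest.raises(ValueError):
            deep.window_spectrum(np.arange(10.0), 0)
        with pytest.raises(ValueError):
            deep.window_spectrum(np.arange(2.0), 3)

    def test_window_matrix_matches_per_spectrum_windowing(self):
        X = np.random.default_rng(0).normal(size=(5, 13))
        W = deep.window_matrix(X, 3)
        assert W.shape == (5, 3, 4)
        for i in range(5):
            per = deep.window_spectrum(X[i], 3)
            assert np.array_equal(W[i], np.stack(per.slices))


class TestAugmentation:
    def test_zero_pct_is_identity(self):
        w = np.linspace(0, 1, 50)
        rng = np.random.default_rng(0)
        assert np.allclose(deep.augment_value(w, 0.0, rng), w)
        assert np.allclose(deep.augment_frequency(w, 0.0, rng), w)

    def test_value_bounded_elementwise(self):
        rng = np.random.default_rng(1)
        w = np.abs(rng.normal(size=200)) + 0.1
        for _ in range(50):
            out = deep.augment_value(w, 10.0, rng)
            assert np.all(out >= 0.9 * w - 1e-12)
            assert np.all(out <= 1.1 * w + 1e-12)

    def test_value_mean_preserving(self):
        """The multiplicative perturbation has unit mean: averaging many
        augmented copies recovers the input to < 1% relative error."""
        rng = np.random.default_rng(2)
        w = np.linspace(1.0, 2.0, 20)
        mean = np.mean([deep.augment_value(w, 10.0, rng) for _ in range(10_000)],
                       axis=0)
        assert np.max(np.abs(mean - w) / w) < 0.01

    def test_frequency_peak_displacement_bounded(self):
        w = np.exp(-0.5 * ((np.arange(200) - 100) / 3.0) ** 2)
        rng = np.random.default_rng(3)
        for _ in range(50):
            out = deep.augment_frequency(w, 10.0, rng)
            assert abs(int(np.argmax(out)) - 100) <= 0.1 * w.size + 1

    def test_frequency_round_trip_recovers_interior(self):
        w = np.sin(np.linspace(0.0, 6.0 * np.pi, 300))
        d = 7.3
        back = deep.frequency_shift(deep.frequency_shift(w, d), -d)
        interior = slice(20, 280)
        assert np.max(np.abs(back[interior] - w[interior])) < 5e-3

    def test_negative_pct_rejected(self):
        with pytest.raises(ValueError):
            deep.augment_value(np.ones(5), -1.0)


class TestBuildModel:
    @pytest.mark.parametrize("n_layers", [25, 56])
    def test_manifest_length_matches_layer_count(self, n_layers):
        cfg = _tiny_cfg(n_layers=n_layers)
        assert len(deep.layer_manifest(cfg)) == n_layers

    def test_invalid_layer_count_rejected(self):
        with pytest.raises(ValueError):
            _tiny_cfg(n_layers=30)

    def test_builds_are_deterministic(self):
        cfg = _tiny_cfg()
        m1, m2 = deep.build_model(cfg), deep.build_model(cfg)
        assert m1.n_parameters() == m2.n_parameters()
        assert all(np.array_equal(a, b) for a, b in zip(m1.params, m2.params))

    def test_deeper_architecture_has_more_parameters(self):
        small = deep.build_model(_tiny_cfg(n_layers=25))
        large = deep.build_model(_tiny_cfg(n_layers=56))
        assert large.n_parameters() > small.n_parameters()

    def test_softmax_output_normalized(self):
        cfg = _tiny_cfg()
        model = deep.build_model(cfg)
        Xw = np.random.default_rng(0).normal(size=(4, cfg.k_s,
                                                   cfg.n_points // cfg.k_s))
        probs = model.predict_proba(Xw)
        assert probs.shape == (4, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs >= 0)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full selective objective agree with
        central finite differences at randomly probed parameters."""
        cfg = _tiny_cfg(reject_threshold=0.8)
        model = deep.build_model(cfg)
        rng = np.random.default_rng(0)
        Xw = rng.normal(size=(3, cfg.k_s, cfg.n_points // cfg.k_s))
        y = np.array([0, 1, 0])
        model.loss_and_backward(Xw, y)
        grads = [g.copy() for g in model.grads]
        probe = np.random.default_rng(1)
        for p, g in zip(model.params, grads):
            for _ in range(2):
                idx = tuple(probe.integers(0, s) for s in p.shape)
                eps = 1e-6
                orig = p[idx]
                p[idx] = orig + eps
                lp = model.loss_and_backward(Xw, y)
                p[idx] = orig - eps
                lm = model.loss_and_backward(Xw, y)
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(numeric, abs=1e-7, rel=1e-4)

    def test_plain_cross_entropy_gradients_also_verify(self):
        cfg = _tiny_cfg(reject_threshold=None)
        model = deep.build_model(cfg)
        rng = np.random.default_rng(2)
        Xw = rng.normal(size=(2, cfg.k_s, cfg.n_points // cfg.k_s))
        y = np.array([1, 0])
        model.loss_and_backward(Xw, y)
        grads = [g.copy() for g in model.grads]
        probe = np.random.default_rng(3)
        for p, g in zip(model.params, grads):
            idx = tuple(probe.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp = model.loss_and_backward(Xw, y)
            p[idx] = orig - eps
            lm = model.loss_and_backward(Xw, y)
            p[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps),
                                           abs=1e-7, rel=1e-4)


class TestSelectivePredict:
    def _model_and_data(self):
        cfg = _tiny_cfg(reject_threshold=0.8, seed=5)
        model = deep.build_model(cfg)
        Xw = np.random.default_rng(6).normal(
            size=(30, cfg.k_s, cfg.n_points // cfg.k_s)
        )
        return model, Xw

    def test_zero_threshold_never_rejects(self):
        model, Xw = self._model_and_data()
        preds = deep.selective_predict(model, Xw, 0.0)
        assert all(p.label != deep.REJECT for p in preds)

    def test_unit_threshold_rejects_all_uncertain(self):
        model, Xw = self._model_and_data()
        preds = deep.selective_predict(model, Xw, 1.0)
        assert all(
            (p.label == deep.REJECT) == (p.confidence < 1.0) for p in preds
        )

    def test_rejection_fraction_monotone_in_threshold(self):
        model, Xw = self._model_and_data()
        fractions = []
        for thr in np.linspace(0, 1, 21):
            preds = deep.selective_predict(model, Xw, thr)
            fractions.append(np.mean([p.label == deep.REJECT for p in preds]))
        assert np.all(np.diff(fractions) >= 0)

    def test_reject_iff_confidence_below_threshold(self):
        model, Xw = self._model_and_data()
        for p in deep.selective_predict(model, Xw, 0.5):
            assert (p.label == deep.REJECT) == (p.confidence < 0.5)

    def test_invalid_threshold_rejected(self):
        model, Xw = self._model_and_data()
        with pytest.raises(ValueError):
            deep.selective_predict(model, Xw, 1.5)


class TestTPE:
    SPACE = {
        "x": ("uniform", -2.0, 2.0),
        "lr": ("loguniform", 1e-4, 0.05),
        "mode": ("choice", ("a", "b")),
    }

    @staticmethod
    def _objective(params):
        return -(params["x"] - 0.7) ** 2 + (1.0 if params["mode"] == "b" else 0.0)

    def test_single_trial_budget_returns_that_sample(self):
        best, history = deep.tpe_maximize(self._objective, self.SPACE, budget=1,
                                          seed=0)
        assert len(history) == 1
        assert best == history[0][0]

    def test_running_best_non_decreasing_with_budget(self):
        _, short = deep.tpe_maximize(self._objective, self.SPACE, budget=10,
                                     seed=1)
        _, long = deep.tpe_maximize(self._objective, self.SPACE, budget=25,
                                    seed=1)
        assert max(v for _, v in long) >= max(v for _, v in short)

    def test_samples_respect_bounds(self):
        _, history = deep.tpe_maximize(self._objective, self.SPACE, budget=30,
                                       seed=2)
        for params, _ in history:
            assert -2.0 <= params["x"] <= 2.0
            assert 1e-4 <= params["lr"] <= 0.05
            assert params["mode"] in ("a", "b")

    def test_beats_plain_random_search_on_smooth_objective(self):
        """Adaptive sampling should concentrate near the optimum and find a
        better value than its own start-up (random) phase."""
        _, history = deep.tpe_maximize(self._objective, self.SPACE, budget=40,
                                       seed=3)
        startup_best = max(v for _, v in history[:8])
        assert max(v for _, v in history) >= startup_best

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            deep.tpe_maximize(self._objective, self.SPACE, budget=0)

    def test_hpo_tpe_returns_valid_config(self):
        def cheap(params):
            return -abs(params["learning_rate"] - 0.01) - params["dropout"]

        cfg, history = deep.hpo_tpe(objective=cheap, budget=12, seed=4,
                                    base_cfg=_tiny_cfg())
        assert isinstance(cfg, deep.NetConfig)
        assert 1e-4 <= cfg.learning_rate <= 0.05
        assert 0.1 <= cfg.dropout <= 0.25
        assert cfg.n_layers in (25, 56)
        assert len(history) == 12
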