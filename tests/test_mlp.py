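import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcgs import MLPConfig, adam_step, hl_bounds, train_mlp
from dcgs.mlp import (
    GridSpec,
    OptimizerState,
    _classification_winner,
    _regression_winner,
    grid_search,
)


class TestHlBounds:
    @pytest.mark.parametrize(
        "m,q,expected",
        [(12, 1, (10, 2)), (100, 1, (28, 5)), (1, 1, (2, 1)), (214, 3, (45, 19))],
    )
    def test_formula_values(self, m, q, expected):
        assert hl_bounds(m, q) == expected

    @given(q=st.integers(1, 5), m=st.integers(1, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_m(self, q, m):
        u1a, u2a = hl_bounds(m, q)
        u1b, u2b = hl_bounds(m + 1, q)
        assert u1b >= u1a and u2b >= u2a

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hl_bounds(0, 1)


class TestAdamStep:
    def _cfg(self, lr=0.005):
        return MLPConfig(learning_rate=lr)

    def test_zero_gradient_no_motion(self):
        state = OptimizerState(np.zeros(3), np.zeros(3))
        for _ in range(5):
            state, delta = adam_step(state, np.zeros(3), self._cfg())
            assert np.all(delta == 0.0)

    def test_first_step_magnitude(self):
        state = OptimizerState(np.zeros(1), np.zeros(1))
        _, delta = adam_step(state, np.ones(1), self._cfg(lr=0.005))
        assert delta[0] == pytest.approx(-0.005, rel=1e-6)

    def test_constant_gradient_unit_step(self):
        state = OptimizerState(np.zeros(1), np.zeros(1))
        g = np.array([0.37])
        for _ in range(2000):
            state, delta = adam_step(state, g, self._cfg(lr=0.005))
        assert abs(delta[0]) == pytest.approx(0.005, rel=1e-3)

    def test_descent_on_convex_mae(self):
        # single linear unit y = w*x under MAE: gradient is piecewise
        # constant, so far from the optimum Adam must strictly descend
        x = np.array([1.0, 2.0, 3.0])
        w_true = 1.0
        w = 0.0
        cfg = self._cfg(lr=0.001)
        state = OptimizerState(np.zeros(1), np.zeros(1))
        losses = []
        for _ in range(100):
            resid = w * x - w_true * x
            losses.append(np.abs(resid).mean())
            grad = np.array([(np.sign(resid) * x).mean()])
            state, delta = adam_step(state, grad, cfg)
            w += delta[0]
        assert all(b <= a + 1e-6 for a, b in zip(losses, losses[1:]))
        assert losses[-1] < losses[0]


class TestTraining:
    def test_deterministic_loss_trace(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        cfg = MLPConfig(n1=6, n2=3, epochs=30, seed=5)
        n1 = train_mlp(X, y, cfg)
        n2 = train_mlp(X, y, cfg)
        assert n1.loss_trace == n2.loss_trace
        assert np.array_equal(n1.predict(X), n2.predict(X))

    def test_constant_target_learned_by_bias(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 5))
        c = 0.5
        net = train_mlp(X, np.full(50, c), MLPConfig(n1=4, n2=2, seed=0))
        assert np.all(np.abs(net.predict(X) - c) < abs(c) * 1e-2 + 1e-2)

    def test_linear_function_converges(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, size=(200, 1))
        y = 2.0 * x[:, 0]
        net = train_mlp(x, y, MLPConfig(n1=8, n2=4, activation="relu", learning_rate=0.005, seed=0))
        assert net.loss_trace[-1] < 0.1

    @pytest.mark.parametrize("loss", ["mae", "cross_entropy"])
    def test_separable_classification_perfect_training_accuracy(self, loss):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, size=(40, 4)), rng.normal(3, 0.3, size=(40, 4))])
        y = np.array(["A"] * 40 + ["B"] * 40)
        net = train_mlp(X, y, MLPConfig(n1=6, n2=3, seed=0, loss=loss), task="classification")
        assert np.mean(net.predict(X) == y) == 1.0
        assert net.loss_trace[-1] < net.loss_trace[0]

    def test_non_finite_loss_names_epoch(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 2))
        y = np.full(20, np.inf)
        with pytest.raises(RuntimeError, match="epoch 0"):
            train_mlp(X, y, MLPConfig(n1=2, n2=2, epochs=5, seed=0))

    def test_non_finite_inputs_rejected(self):
        X = np.full((20, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            train_mlp(X, np.zeros(20), MLPConfig(n1=2, n2=2, seed=0))

    def test_serialization_roundtrip(self):
        from dcgs.mlp import MLPNetwork

        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        net = train_mlp(X, y, MLPConfig(n1=3, n2=2, epochs=10, seed=1))
        net2 = MLPNetwork.from_dict(net.to_dict())
        assert np.allclose(net.predict(X), net2.predict(X))


class TestGridSearch:
    def _rec(self, n1, n2, r, mape_):
        return {"config": MLPConfig(n1=n1, n2=n2), "r": r, "mape": mape_, "loss": 0.0}

    def test_dominating_config_wins(self):
        recs = [self._rec(2, 2, 0.8, 10.0), self._rec(3, 3, 0.8, 20.0)]
        assert _regression_winner(recs) == 0

    def test_corner_rule_tie_broken_by_raw_r(self):
        recs = [self._rec(2, 2, 0.9, 10.0), self._rec(3, 3, 0.5, 5.0)]
        assert _regression_winner(recs) == 0

    def test_order_invariance_up_to_documented_ties(self):
        recs = [
            self._rec(2, 2, 0.7, 12.0),
            self._rec(4, 4, 0.9, 8.0),
            self._rec(3, 3, 0.4, 30.0),
        ]
        win_cfg = recs[_regression_winner(recs)]["config"]
        rev = list(reversed(recs))
        assert rev[_regression_winner(rev)]["config"] == win_cfg

    def test_classification_tie_broken_by_loss(self):
        recs = [
            {"config": MLPConfig(n1=2, n2=2), "accuracy": 1.0, "loss": 0.3},
            {"config": MLPConfig(n1=3, n2=2), "accuracy": 1.0, "loss": 0.1},
            {"config": MLPConfig(n1=4, n2=2), "accuracy": 0.9, "loss": 0.01},
        ]
        assert _classification_winner(recs) == 1

    def test_grid_spec_respects_bounds(self):
        spec = GridSpec.from_data(100, 1, points_per_layer=8)
        u1, u2 = hl_bounds(100, 1)
        assert max(spec.n1_candidates) == u1 and min(spec.n1_candidates) == 1
        assert max(spec.n2_candidates) == u2
        assert len(spec.n1_candidates) <= 8

    def test_end_to_end_small_grid(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 5))
        y = X[:, 0] * 2.0 + rng.normal(0, 0.1, 80)
        spec = GridSpec(
            n1_candidates=(8,), n2_candidates=(4,), activations=("relu",), learning_rates=(0.005,)
        )
        res = grid_search(X, y, spec, seed=0)
        assert len(res.records) == 1
        assert res.records[0]["r"] > 0.5

    def test_empty_grid_rejected(self):
        spec = GridSpec(n1_candidates=(), n2_candidates=(2,))
        with pytest.raises(ValueError, match="empty"):
            spec.configs()
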