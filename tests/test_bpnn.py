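"""Feed-forward network, LM training, and the architecture search."""

import numpy as np
import pytest

from asriskmap.bpnn import (
    NetworkParams, NetworkSpec, SearchReport, TrainConfig, TrainedNetwork,
    TrainingDivergence, architecture_search, fit_network, forward, init_params,
    jacobian, lm_train, table4_candidates,
)


def _params(spec, seed=0):
    return init_params(NetworkSpec(spec), np.random.default_rng(seed))


def _bumps(X):
    """Smooth test surface: sum of two Gaussian bumps on [-1, 1]^2."""
    return (np.exp(-((X[:, 0] - 0.4) ** 2 + (X[:, 1] - 0.3) ** 2) / 0.1)
            - 0.8 * np.exp(-((X[:, 0] + 0.5) ** 2 + (X[:, 1] + 0.4) ** 2) / 0.15))


class TestForward:
    def test_all_zero_parameters_give_zero_output(self):
        spec = NetworkSpec((2, 3, 1))
        p = NetworkParams.unflatten(spec, np.zeros(spec.n_params))
        assert forward(p, [(0.3, -0.7), (1.0, 1.0)]) == pytest.approx([0.0, 0.0])

    def test_single_hidden_neuron_bias_is_subtracted(self):
        # W1 = 0, b1 = beta, output weight 1, output bias 0 -> tanh(-beta)
        beta = 0.8
        p = NetworkParams(
            (np.zeros((1, 2)), np.array([[1.0]])),
            (np.array([beta]), np.array([0.0])),
        )
        assert forward(p, (0.2, -0.5)) == pytest.approx(np.tanh(-beta), rel=1e-14)

    def test_hand_computed_two_hidden_neurons(self):
        p = NetworkParams(
            (np.array([[0.5, -0.25], [0.1, 0.3]]), np.array([[1.0, -2.0]])),
            (np.array([0.2, -0.4]), np.array([0.1])),
        )
        # frozen manual evaluation: tanh(0.55) - 2*tanh(0.2) - 0.1
        assert forward(p, (1.0, -1.0)) == pytest.approx(
            0.005769570740427193, abs=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="input dimension"):
            forward(_params((2, 3, 1)), np.ones((4, 3)))

    def test_spec_validation(self):
        for bad in [(3, 4, 1), (2, 4, 2), (2, 1), (2, 3, 3, 3, 1), (2, 0, 1)]:
            with pytest.raises(ValueError):
                NetworkSpec(bad)

    def test_flatten_round_trip(self):
        spec = NetworkSpec((2, 4, 3, 1))
        p = _params((2, 4, 3, 1), seed=2)
        q = NetworkParams.unflatten(spec, p.flatten())
        for w1, w2 in zip(p.weights, q.weights):
            np.testing.assert_array_equal(w1, w2)


class TestJacobian:
    @pytest.mark.parametrize("sizes,seed", [((2, 3, 1), 0), ((2, 4, 3, 1), 1)])
    def test_matches_finite_differences(self, sizes, seed):
        spec = NetworkSpec(sizes)
        p = _params(sizes, seed)
        X = np.random.default_rng(seed + 10).uniform(-1, 1, (7, 2))
        J = jacobian(p, X)
        theta = p.flatten()
        eps = 1e-6
        for k in range(spec.n_params):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            fd = (forward(NetworkParams.unflatten(spec, tp), X)
                  - forward(NetworkParams.unflatten(spec, tm), X)) / (2 * eps)
            np.testing.assert_allclose(J[:, k], fd, rtol=1e-4, atol=1e-8)


class TestLMTraining:
    def _linear_data(self, seed, n=50):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, (n, 2))
        return X, 0.3 * X[:, 0] - 0.2 * X[:, 1] + 0.1

    def test_linear_function_reaches_mse_goal(self):
        ok = 0
        for seed in range(10):
            X, y = self._linear_data(99)
            cfg = TrainConfig(mse_goal=1e-2, max_epochs=200, seed=seed)
            _, hist = lm_train(NetworkSpec((2, 2, 1)), (X, y), cfg)
            ok += hist.converged and hist.n_epochs <= 200
        assert ok >= 9

    def test_accepted_steps_never_increase_mse(self):
        X = np.random.default_rng(0).uniform(-1, 1, (60, 2))
        y = _bumps(X)
        cfg = TrainConfig(mse_goal=1e-8, max_epochs=60, seed=1)
        _, hist = lm_train(NetworkSpec((2, 6, 1)), (X, y), cfg)
        assert np.all(np.diff(hist.mse) <= 1e-15)

    def test_identical_seed_is_bit_reproducible(self):
        X, y = self._linear_data(5)
        cfg = TrainConfig(mse_goal=1e-6, max_epochs=50, seed=42)
        p1, h1 = lm_train(NetworkSpec((2, 4, 1)), (X, y), cfg)
        p2, h2 = lm_train(NetworkSpec((2, 4, 1)), (X, y), cfg)
        np.testing.assert_array_equal(p1.flatten(), p2.flatten())
        assert h1.mse == h2.mse

    def test_large_damping_steps_toward_the_gradient(self):
        X, y = self._linear_data(6)
        spec = NetworkSpec((2, 3, 1))
        p = _params((2, 3, 1), seed=3)
        J = jacobian(p, X)
        r = forward(p, X) - y
        g = J.T @ r
        lam = 1e9
        delta = np.linalg.solve(J.T @ J + lam * np.eye(spec.n_params), -g)
        cos = (delta @ -g) / (np.linalg.norm(delta) * np.linalg.norm(g))
        assert cos == pytest.approx(1.0, abs=1e-4)

    def test_infinite_goal_returns_initial_parameters(self):
        X, y = self._linear_data(7)
        cfg = TrainConfig(mse_goal=np.inf, max_epochs=100, seed=0)
        params, hist = lm_train(NetworkSpec((2, 2, 1)), (X, y), cfg)
        assert hist.n_epochs == 0 and len(hist.mse) == 1 and hist.converged
        expected = init_params(NetworkSpec((2, 2, 1)), np.random.default_rng(0))
        np.testing.assert_array_equal(params.flatten(), expected.flatten())

    def test_requires_enough_finite_data(self):
        with pytest.raises(ValueError):
            lm_train(NetworkSpec((2, 2, 1)), (np.zeros((5, 2)), np.zeros(5)))
        X = np.zeros((12, 2))
        y = np.full(12, np.nan)
        with pytest.raises(ValueError, match="finite"):
            lm_train(NetworkSpec((2, 2, 1)), (X, y))

    def test_wide_hidden_layer_fits_smooth_surface(self):
        # capacity check: (2, h, 1) with h >= 10 drives mse below 1e-2
        rng = np.random.default_rng(8)
        X = rng.uniform(-1, 1, (120, 2))
        y = _bumps(X)
        ok = 0
        for seed in range(10):
            cfg = TrainConfig(mse_goal=1e-2, max_epochs=300, seed=seed)
            try:
                _, hist = lm_train(NetworkSpec((2, 10, 1)), (X, y), cfg)
            except TrainingDivergence:
                continue
            ok += hist.converged
        assert ok >= 8


class TestTrainedNetwork:
    def test_prediction_invariant_to_coordinate_units(self):
        # meter-scale coordinates are scaled internally before tanh
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 30000, (80, 2))
        y = _bumps(coords / 15000.0 - 1.0)
        net = fit_network(coords, y, NetworkSpec((2, 8, 1)),
                          TrainConfig(mse_goal=1e-3, max_epochs=200, seed=0),
                          restarts=2)
        pred = net.predict(coords)
        assert np.mean((pred - y) ** 2) < 0.05
        scaled = net.scaling.apply(coords)
        assert np.abs(scaled).max() <= 1.0 + 1e-9

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10000, (40, 2))
        y = rng.normal(0, 0.3, 40)
        net = fit_network(coords, y, NetworkSpec((2, 4, 1)),
                          TrainConfig(max_epochs=30, seed=1), restarts=1)
        path = tmp_path / "net.json"
        net.to_json(path)
        loaded = TrainedNetwork.from_json(path)
        np.testing.assert_allclose(loaded.predict(coords), net.predict(coords),
                                   rtol=1e-12)


class TestArchitectureSearch:
    def _folds(self, seed=0, n=150):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 30000, (n, 2))
        y = _bumps(coords / 15000.0 - 1.0)
        out = {}
        for i, lab in enumerate("ABC"):
            sl = slice(i * n // 3, (i + 1) * n // 3)
            out[lab] = (coords[sl], y[sl])
        return out

    def test_single_candidate_is_selected(self):
        report = architecture_search(
            self._folds(), [NetworkSpec((2, 4, 1))],
            TrainConfig(max_epochs=50, seed=0), restarts=1)
        assert report.selected == "(2,4,1)"

    def test_report_covers_every_spec_fold_cell(self):
        cands = [NetworkSpec((2, 2, 1)), NetworkSpec((2, 4, 1))]
        report = architecture_search(
            self._folds(), cands, TrainConfig(max_epochs=30, seed=1), restarts=1)
        assert sorted(report.table["held_out"].unique()) == ["A", "B", "C"]
        assert len(report.table) == len(cands) * 3
        for col in ("train_r2", "val_r2", "train_rmse", "val_rmse"):
            assert col in report.table.columns
        assert set(report.averages.index) == {"(2,2,1)", "(2,4,1)"}

    def test_larger_network_attains_at_least_smaller_validation_r2(self):
        small, big = NetworkSpec((2, 2, 1)), NetworkSpec((2, 10, 10, 1))
        diffs = []
        for seed in range(10):
            report = architecture_search(
                self._folds(), [small, big],
                TrainConfig(mse_goal=1e-5, max_epochs=100, seed=seed), restarts=1)
            avg = report.averages["val_r2"]
            diffs.append(avg["(2,10,10,1)"] - avg["(2,2,1)"])
        assert np.mean(diffs) >= 0.0

    def test_table4_candidate_space(self):
        cands = table4_candidates(range(2, 51, 2), range(0, 51, 2))
        assert len(cands) == 25 * 26
        sizes = {c.layer_sizes for c in cands}
        assert (2, 10, 10, 1) in sizes and (2, 50, 1) in sizes
        assert all(c.layer_sizes[0] == 2 and c.layer_sizes[-1] == 1 for c in cands)
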