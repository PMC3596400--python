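"""Forward-pass oracle equivalence, gradient checks, training contracts."""

import numpy as np
import pytest

from gfrnet.ann import (
    DEFAULT_HIDDEN_RANGE,
    NetworkParameters,
    NetworkTopology,
    TrainingConfig,
    TrainingError,
    forward,
    gradients,
    mse,
    topology_search,
    train_bp,
)


def sum_loop_forward(params, x):
    """Independent scalar-loop oracle for the network forward pass."""
    h, d = params.w_hidden.shape
    out = params.b_output
    for i in range(h):
        z = params.b_hidden[i]
        for j in range(d):
            z += params.w_hidden[i, j] * x[j]
        out += params.w_output[i] / (1.0 + np.exp(-z))
    return out


class TestForward:
    def test_zero_parameters_give_zero_output(self):
        p = NetworkParameters(np.zeros((2, 3)), np.zeros(2), np.zeros(2), 0.0)
        assert forward(p, np.zeros(3)) == 0.0

    def test_single_unit_sigmoid_midpoint(self):
        # zero input weights/threshold -> sigma(0)=0.5; output weight 2 -> 1.0
        p = NetworkParameters(np.zeros((1, 4)), np.zeros(1), np.array([2.0]), 0.0)
        assert forward(p, np.ones(4)) == pytest.approx(1.0)

    @pytest.mark.parametrize("topology", [(6, 2), (7, 11)])
    def test_oracle_equivalence_random_parameterizations(self, topology, rng):
        """100 random networks agree with the sum-loop oracle to 1e-10."""
        d, h = topology
        for _ in range(100):
            p = NetworkParameters.random(NetworkTopology(d, h), rng, scale=2.0)
            x = rng.uniform(0, 1, d)
            assert forward(p, x) == pytest.approx(sum_loop_forward(p, x), abs=1e-10)

    def test_matrix_and_vector_forms_agree(self, rng):
        p = NetworkParameters.random(NetworkTopology(5, 3), rng)
        X = rng.random((10, 5))
        batch = forward(p, X)
        single = np.array([forward(p, row) for row in X])
        np.testing.assert_allclose(batch, single, atol=1e-14)

    def test_shape_mismatch_rejected(self, rng):
        p = NetworkParameters.random(NetworkTopology(5, 3), rng)
        with pytest.raises(ValueError):
            forward(p, np.zeros(4))

    def test_bounded_gradient_in_inputs(self, rng):
        """|d out / d x_j| never exceeds sum_i |v_i W_ij| / 4 (sigma' <= 1/4)."""
        p = NetworkParameters.random(NetworkTopology(4, 6), rng, scale=2.0)
        bound = np.sum(np.abs(p.w_output[:, None] * p.w_hidden), axis=0) / 4.0
        x = rng.random(4)
        eps = 1e-6
        for j in range(4):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            deriv = (forward(p, xp) - forward(p, xm)) / (2 * eps)
            assert abs(deriv) <= bound[j] + 1e-6


class TestMse:
    def test_identical_vectors_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset(self):
        assert mse([3.0, 3.0], [1.0, 1.0]) == pytest.approx(4.0)

    def test_hand_value(self):
        assert mse([0.0, 1.0], [1.0, 0.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse([], [])


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        """Analytic backprop vs central differences on 100 random configurations."""
        worst = 0.0
        for _ in range(100):
            topo = NetworkTopology(int(rng.integers(1, 8)), int(rng.integers(1, 14)))
            p = NetworkParameters.random(topo, rng, scale=1.5)
            X = rng.random((5, topo.n_input))
            y = rng.random(5)
            g = gradients(p, X, y)
            eps = 1e-6
            for name in ("w_hidden", "b_hidden", "w_output"):
                arr = getattr(p, name)
                it = np.nditer(arr, flags=["multi_index"])
                for _v in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp = mse(forward(p, X), y)
                    arr[idx] = orig - eps
                    lm = mse(forward(p, X), y)
                    arr[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    denom = max(abs(fd), 1e-4)
                    worst = max(worst, abs(g[name][idx] - fd) / denom)
        assert worst < 1e-5


class TestTrainBp:
    def test_constant_target_learned(self, rng):
        X = rng.random((50, 3))
        Xv = rng.random((20, 3))
        y = np.full(50, 0.5)
        yv = np.full(20, 0.5)
        p0 = NetworkParameters.random(NetworkTopology(3, 2), rng)
        p, _ = train_bp(X, y, Xv, yv, p0, TrainingConfig(max_epochs=500, patience=0))
        assert mse(forward(p, X), y) < 1e-4

    def test_returned_snapshot_never_worse_than_initial(self, rng):
        X, Xv = rng.random((40, 3)), rng.random((15, 3))
        y, yv = rng.random(40), rng.random(15)
        p0 = NetworkParameters.random(NetworkTopology(3, 4), rng)
        before = mse(forward(p0, Xv), yv)
        p, _ = train_bp(X, y, Xv, yv, p0, TrainingConfig(max_epochs=50, patience=0))
        assert mse(forward(p, Xv), yv) <= before

    def test_running_best_validation_mse_non_increasing(self, rng):
        X, Xv = rng.random((40, 3)), rng.random((15, 3))
        y, yv = rng.random(40), rng.random(15)
        p0 = NetworkParameters.random(NetworkTopology(3, 4), rng)
        _, hist = train_bp(X, y, Xv, yv, p0, TrainingConfig(max_epochs=300, patience=0))
        assert np.all(np.diff(hist.best_val_mse) <= 0)

    def test_divergence_raises_training_error(self, rng):
        X, Xv = rng.random((20, 2)), rng.random((10, 2))
        y, yv = rng.random(20) * 100, rng.random(10) * 100
        p0 = NetworkParameters.random(NetworkTopology(2, 3), rng)
        with pytest.raises(TrainingError, match="learning rate"):
            train_bp(X, y, Xv, yv, p0, TrainingConfig(learning_rate=1e4, max_epochs=500))

    def test_deterministic_for_fixed_inputs(self, rng):
        X, Xv = rng.random((30, 3)), rng.random((10, 3))
        y, yv = rng.random(30), rng.random(10)
        p0 = NetworkParameters.random(NetworkTopology(3, 2), rng)
        cfg = TrainingConfig(max_epochs=100, patience=0)
        p1, _ = train_bp(X, y, Xv, yv, p0.copy(), cfg)
        p2, _ = train_bp(X, y, Xv, yv, p0.copy(), cfg)
        np.testing.assert_array_equal(p1.w_hidden, p2.w_hidden)

    def test_teacher_network_recovery(self, rng):
        """Training on noiseless data from a random 6-2-1 teacher reaches MSE < 1e-3."""
        teacher = NetworkParameters.random(NetworkTopology(6, 2), rng, scale=1.0)
        X, Xv = rng.random((562, 6)), rng.random((269, 6))
        y, yv = forward(teacher, X), forward(teacher, Xv)
        student0 = NetworkParameters.random(NetworkTopology(6, 2), rng)
        p, _ = train_bp(X, y, Xv, yv, student0, TrainingConfig(seed=0))
        assert mse(forward(p, Xv), yv) < 1e-3


class TestTopologySearch:
    def test_default_candidate_range(self):
        assert list(DEFAULT_HIDDEN_RANGE) == list(range(1, 14))

    def test_argmin_contract_with_injected_trainer(self):
        """A trainer whose validation MSE is |h-4| makes h=4 the winner."""
        X = np.zeros((4, 2))
        y = np.zeros(4)

        def fake_trainer(Xd, yd, Xv, yv, initial, config):
            h = initial.topology.n_hidden
            # constant-output network: MSE vs zero targets = b_output^2 = |h-4|
            p = NetworkParameters(
                np.zeros((h, 2)), np.zeros(h), np.zeros(h), np.sqrt(abs(h - 4))
            )
            return p, None

        topo, table = topology_search(X, y, X, y, range(1, 14), trainer=fake_trainer)
        assert topo.n_hidden == 4
        assert table[6] == pytest.approx(2.0)

    def test_tie_breaks_toward_fewer_units(self):
        X = np.zeros((4, 2))
        y = np.zeros(4)

        def fake_trainer(Xd, yd, Xv, yv, initial, config):
            h = initial.topology.n_hidden
            val = 0.0 if h in (2, 3) else 1.0
            p = NetworkParameters(np.zeros((h, 2)), np.zeros(h), np.zeros(h), np.sqrt(val))
            return p, None

        topo, _ = topology_search(X, y, X, y, range(1, 14), trainer=fake_trainer)
        assert topo.n_hidden == 2

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            topology_search(np.zeros((2, 1)), np.zeros(2), np.zeros((2, 1)), np.zeros(2), [0, 5])
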