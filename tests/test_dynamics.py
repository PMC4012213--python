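import numpy as np
import pytest

from rewardnet import (
    NetworkState,
    PlasticityParams,
    WeightSet,
    embed_memories,
    feedforward_derivative,
    initial_state_near,
    make_memory_set,
    rate_derivative,
    recurrent_derivative,
    run_simulation,
    step,
)
from rewardnet.errors import InstabilityError, ParameterError, ShapeError
from rewardnet.stimulus import StimulusRewardPattern, StimulusTemplate, zero_pattern


def constant_pattern(T, u=1.0, r=0.0):
    """Constant binary stimulus u with constant reward r, for T steps."""
    stim = StimulusTemplate("chronic", np.full(T, 1.0 if u else 0.0), onset=0)
    return StimulusRewardPattern(stim, np.full(T, float(r)), ("test", "test"))


class TestDerivatives:
    def test_rate_all_zero(self):
        w = WeightSet(np.zeros((3, 3)), np.zeros(3))
        assert (rate_derivative(NetworkState(np.zeros(3)), w, 0.0) == 0).all()

    def test_rate_pure_decay(self):
        v0 = np.array([2.0, -1.0])
        w = WeightSet(np.zeros((2, 2)), np.zeros(2))
        np.testing.assert_allclose(rate_derivative(NetworkState(v0), w, 0.0), -v0)

    def test_rate_hand_case(self):
        # v=(1,0), M=I, W=(1,1), u=1 -> (-v + tanh v + W u) = (tanh 1, 1)
        w = WeightSet(np.eye(2), np.ones(2))
        d = rate_derivative(NetworkState(np.array([1.0, 0.0])), w, 1.0)
        np.testing.assert_allclose(d, [np.tanh(1.0), 1.0])

    def test_feedforward_zero_when_prediction_exact(self):
        w = WeightSet(np.zeros((2, 2)), np.array([0.3, 0.7]))
        d = feedforward_derivative(w, 1.0, 0.5, np.full(2, 0.5))
        np.testing.assert_allclose(d, 0.0)

    def test_feedforward_zero_when_autonomous(self):
        w = WeightSet(np.eye(3), np.ones(3))  # M = I so K = 0
        d = feedforward_derivative(w, 1.0, 2.0, np.zeros(3))
        np.testing.assert_allclose(d, 0.0)

    def test_feedforward_hand_case(self):
        # K=I (M=0), W=(1,1), u=1, r=0.5, v=0 -> (0.5, 0.5)
        w = WeightSet(np.zeros((2, 2)), np.ones(2))
        d = feedforward_derivative(w, 1.0, 0.5, np.zeros(2))
        np.testing.assert_allclose(d, [0.5, 0.5])

    def test_recurrent_zero_at_identity_no_input(self):
        w = WeightSet(np.eye(4), np.ones(4))
        np.testing.assert_allclose(recurrent_derivative(w, 0.0, np.ones(4)), 0.0)

    def test_recurrent_relaxation_toward_identity(self, rng):
        M = rng.normal(size=(3, 3))
        w = WeightSet(M, np.ones(3))
        np.testing.assert_allclose(
            recurrent_derivative(w, 0.0, rng.normal(size=3)), np.eye(3) - M
        )

    def test_recurrent_hand_outer_product(self):
        # M=I, W=(1,0), u=1, v=(0,1) -> -outer((1,0),(0,1)) = [[0,-1],[0,0]]
        w = WeightSet(np.eye(2), np.array([1.0, 0.0]))
        d = recurrent_derivative(w, 1.0, np.array([0.0, 1.0]))
        np.testing.assert_allclose(d, [[0.0, -1.0], [0.0, 0.0]])

    def test_shape_errors(self):
        w = WeightSet(np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ShapeError):
            rate_derivative(NetworkState(np.zeros(3)), w, 0.0)
        with pytest.raises(ShapeError):
            feedforward_derivative(w, 1.0, 0.0, np.zeros(3))
        with pytest.raises(ShapeError):
            recurrent_derivative(w, 1.0, np.zeros(3))


class TestStep:
    def test_global_fixed_point(self):
        w = WeightSet(np.zeros((3, 3)), np.zeros(3))
        params = PlasticityParams(dt=0.05)
        s2, w2 = step(NetworkState(np.zeros(3)), w, zero_pattern(10), params)
        assert (s2.v == 0).all() and (w2.W == 0).all()
        np.testing.assert_allclose(w2.M, w.M + 0.05 * np.eye(3) / params.tau_M)

    def test_frozen_weights_bit_identical(self, rng):
        M = rng.normal(size=(4, 4))
        W = rng.normal(size=4)
        w = WeightSet(M.copy(), W.copy())
        params = PlasticityParams(plastic_W=False, plastic_M=False, dt=0.05)
        pat = constant_pattern(10, u=1.0, r=0.7)
        _, w2 = step(NetworkState(rng.normal(size=4)), w, pat, params)
        assert (w2.M == M).all() and (w2.W == W).all()

    def test_step_composes_the_three_derivatives(self, rng):
        # oracle: evaluate the derivative operations independently and apply
        # one manual Euler update
        M = rng.normal(size=(2, 2)) * 0.1
        W = rng.normal(size=2)
        v = rng.normal(size=2)
        w = WeightSet(M.copy(), W.copy())
        params = PlasticityParams(tau_v=1.0, tau_W=5.0, tau_M=4.0, epsilon=0.3, dt=0.05)
        pat = constant_pattern(10, u=1.0, r=0.9)
        state2, w2 = step(NetworkState(v.copy()), w, pat, params)

        dv = rate_derivative(NetworkState(v), WeightSet(M, W), 1.0) / 1.0
        dW = 0.3 * feedforward_derivative(WeightSet(M, W), 1.0, 0.9, v) / 5.0
        dM = recurrent_derivative(WeightSet(M, W), 1.0, v) / 4.0
        np.testing.assert_allclose(state2.v, v + 0.05 * dv, atol=1e-14)
        np.testing.assert_allclose(w2.W, W + 0.05 * dW, atol=1e-14)
        np.testing.assert_allclose(w2.M, M + 0.05 * dM, atol=1e-14)

    def test_instability_error_names_step(self):
        w = WeightSet(np.zeros((2, 2)), np.full(2, 10.0))
        params = PlasticityParams(dt=0.05, divergence_bound=0.1)
        pat = constant_pattern(10, u=1.0, r=0.0)
        with pytest.raises(InstabilityError) as exc:
            step(NetworkState(np.zeros(2)), w, pat, params)
        assert exc.value.t == 0

    def test_dt_validation(self):
        with pytest.raises(ParameterError):
            PlasticityParams(tau_v=1.0, dt=0.5)
        with pytest.raises(ParameterError):
            PlasticityParams(tau_v=-1.0)


class TestRunSimulation:
    def test_zero_network_fair_coin_raster(self):
        w = WeightSet(np.zeros((8, 8)), np.zeros(8))
        params = PlasticityParams(plastic_W=False, plastic_M=False, dt=0.05)
        trace = run_simulation(NetworkState(np.zeros(8)), w, zero_pattern(400), params, seed=0)
        assert (trace.v_history == 0).all()
        assert abs(trace.spike_raster.mean() - 0.5) < 0.02  # logistic(0) = 1/2

    def test_seeded_reproducibility(self, rng):
        mem = make_memory_set((rng.random((2, 8)) < 0.4).astype(float) + 0.0, alpha=0.4)
        w = WeightSet(embed_memories(mem, uniform_offset=False).M, np.full(8, 0.05))
        params = PlasticityParams(dt=0.05)
        pat = constant_pattern(30, u=1.0, r=0.5)
        t1 = run_simulation(NetworkState(np.zeros(8)), w, pat, params, seed=42)
        t2 = run_simulation(NetworkState(np.zeros(8)), w, pat, params, seed=42)
        assert (t1.spike_raster == t2.spike_raster).all()
        assert (t1.v_history == t2.v_history).all()
        assert (t1.energy == t2.energy).all()

    def test_embedded_pattern_retained_frozen_weights(self, rng):
        # one sparse pattern at N=8; starting on the pattern with u == 0,
        # rates must stay in its neighbourhood (sign pattern preserved)
        pattern = np.array([1.0, 0, 0, 1, 0, 1, 0, 0])
        rec = embed_memories(make_memory_set(pattern[None, :]), uniform_offset=False)
        w = WeightSet(rec.M, np.zeros(8))
        params = PlasticityParams(plastic_W=False, plastic_M=False, dt=0.05)
        trace = run_simulation(NetworkState(pattern.copy()), w, zero_pattern(100), params, seed=1)
        v_end = trace.v_history[-1]
        assert (v_end[pattern == 1] > 0.5).all()
        assert (v_end[pattern == 0] < 0.0).all()

    def test_euler_first_order_convergence(self, rng):
        M = 0.2 * rng.normal(size=(4, 4))
        W = rng.normal(size=4)
        pat = constant_pattern(50, u=1.0, r=0.3)
        finals = {}
        for dt in (0.1, 0.05, 0.025):
            params = PlasticityParams(plastic_W=False, plastic_M=False, dt=dt)
            trace = run_simulation(NetworkState(np.zeros(4)), WeightSet(M, W), pat, params, seed=0)
            finals[dt] = trace.v_history[-1]
        err_coarse = np.linalg.norm(finals[0.1] - finals[0.025])
        err_fine = np.linalg.norm(finals[0.05] - finals[0.025])
        assert err_fine < err_coarse  # O(dt) shrinkage

    def test_rescorla_wagner_convergence(self):
        # M frozen at 0 (so K = I), u = 1, constant r: the prediction v
        # converges to r with error < 1e-3 within 50 tau_W steps
        tau_W = 20.0
        T = int(50 * tau_W)
        N = 4
        w = WeightSet(np.zeros((N, N)), np.full(N, 0.2))
        params = PlasticityParams(tau_W=tau_W, plastic_M=False, dt=0.05, epsilon=1.0)
        pat = constant_pattern(T, u=1.0, r=0.8)
        trace = run_simulation(NetworkState(np.zeros(N)), w, pat, params, seed=0)
        err = np.abs(0.8 - trace.v_history[-1])
        assert (err < 1e-3).all()

    def test_goodall_relaxation_closed_form(self, rng):
        # u == 0: ||M(t) - I||_F decays as exp(-t / tau_M)
        tau_M = 20.0
        M0 = np.eye(6) + 0.5 * rng.normal(size=(6, 6))
        w = WeightSet(M0.copy(), np.zeros(6))
        params = PlasticityParams(tau_M=tau_M, plastic_W=False, dt=0.05,
                                  divergence_bound=1e6)
        T = int(3 * tau_M) + 1
        trace = run_simulation(NetworkState(np.zeros(6)), w, zero_pattern(T), params,
                               seed=0, snapshot_every=1)
        d0 = np.linalg.norm(M0 - np.eye(6))
        for t in (int(tau_M), int(3 * tau_M)):
            dt_norm = np.linalg.norm(trace.M_history[t] - np.eye(6))
            assert dt_norm == pytest.approx(d0 * np.exp(-t / tau_M), rel=0.05)

    def test_initial_state_near_flips_requested_fraction(self):
        pattern = np.zeros(100)
        pattern[:30] = 1
        state = initial_state_near(pattern, flip_fraction=0.1, seed=3)
        assert int(np.sum(state.v != pattern)) == 10
        assert set(np.unique(state.v)) <= {0.0, 1.0}
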