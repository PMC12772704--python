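"""Integrator correctness and dynamical observables on controlled cases."""

import math

import numpy as np
import pytest

from recnets import (
    EnsembleParams,
    ParameterError,
    SimConfig,
    WeightMatrix,
    activity_stats,
    find_fixed_points,
    integrate,
    jacobian_at,
    lyapunov_max,
    participation_ratio,
    path_length,
    sample_weights,
    simulate_ensemble,
)
from recnets.dynamics import Trajectory


def make_config(**kw):
    defaults = dict(t_transient=0.0, t_measure=50.0, t_max=50.0, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestIntegrate:
    def test_decoupled_units_decay_exponentially(self, zero_matrix):
        x0 = np.ones(10)
        traj = integrate(zero_matrix, make_config(t_max=20.0, t_measure=20.0), x0=x0)
        # state halves every ln(2) time units
        for k in (50, 100, 200):
            t = traj.times[k]
            assert traj.states[k, 0] == pytest.approx(math.exp(-t), rel=1e-6)

    def test_derivative_record_matches_vector_field(self, draw_weights):
        W = draw_weights(20, 0.2, g=1.0, seed=3)
        traj = integrate(W, make_config(t_max=5.0, t_measure=5.0))
        for k in (0, 10, -1):
            expected = -traj.states[k] + W.values @ np.tanh(traj.states[k])
            assert np.allclose(traj.derivs[k], expected)

    def test_below_onset_contracts_to_origin(self, draw_weights):
        W = draw_weights(200, 0.0, geff=0.5, seed=2)
        traj = integrate(W, make_config(t_max=100.0, t_measure=100.0))
        assert traj.converged
        assert traj.t_fp is not None
        assert np.linalg.norm(traj.states[-1]) < 1e-6 * math.sqrt(200)

    def test_chaotic_regime_does_not_converge(self, draw_weights):
        W = draw_weights(300, 0.0, geff=1.4, seed=5)
        traj = integrate(W, make_config(t_max=200.0, t_measure=200.0))
        assert not traj.converged
        assert traj.t_fp is None

    def test_global_error_scales_as_fourth_order(self, zero_matrix):
        # W=0 closed form x(t) = x0 e^{-t}: classical RK4 convergence
        errs = []
        for dt in (0.1, 0.05, 0.025):
            cfg = SimConfig(dt=dt, t_transient=0.0, t_measure=5.0, t_max=5.0,
                            max_samples=10000)
            traj = integrate(zero_matrix, cfg, x0=np.ones(10))
            errs.append(abs(traj.states[-1, 0] - math.exp(-5.0)))
        r1 = errs[0] / errs[1]
        r2 = errs[1] / errs[2]
        assert 4 < r1 < 64  # 16 within a factor of 4
        assert 4 < r2 < 64

    def test_invalid_initial_condition_rejected(self, zero_matrix):
        with pytest.raises(ParameterError):
            integrate(zero_matrix, make_config(), x0=np.full(10, np.nan))


class TestJacobian:
    def test_at_origin_equals_coupling_minus_identity(self, draw_weights):
        W = draw_weights(30, 0.1, g=1.2, seed=1)
        J = jacobian_at(W, np.zeros(30))
        assert np.allclose(J, -np.eye(30) + W.values)

    def test_saturation_contracts_to_negative_identity(self, draw_weights):
        W = draw_weights(30, 0.1, g=1.2, seed=1)
        J = jacobian_at(W, 50.0 * np.ones(30))
        assert np.allclose(J, -np.eye(30), atol=1e-12)
        assert np.max(np.linalg.eigvals(J).real) == pytest.approx(-1.0, abs=1e-12)

    def test_origin_edge_matches_effective_gain(self, draw_weights):
        # rightmost eigenvalue of J(0) = -I + W sits near geff - 1
        W = draw_weights(1500, 0.25, geff=1.2, seed=8)
        J = jacobian_at(W, np.zeros(1500))
        edge = np.max(np.linalg.eigvals(J).real)
        assert edge == pytest.approx(0.2, abs=0.06)


class TestLyapunov:
    def test_uncoupled_network_has_unit_decay_rate(self, zero_matrix):
        lam = lyapunov_max(zero_matrix, make_config(t_measure=20.0, t_max=None))
        assert lam == pytest.approx(-1.0, abs=1e-3)

    def test_below_onset_equals_spectral_edge(self, draw_weights):
        W = draw_weights(300, 0.0, geff=0.5, seed=4)
        cfg = SimConfig(t_transient=20.0, t_measure=150.0, seed=4)
        lam = lyapunov_max(W, cfg)
        assert lam == pytest.approx(-0.5, abs=0.06)


class TestParticipationRatio:
    def _traj_from_states(self, X):
        cfg = make_config()
        T = X.shape[0]
        return Trajectory(
            times=np.arange(T, dtype=float),
            states=X,
            derivs=np.zeros_like(X),
            converged=False,
            t_fp=None,
            path_cumulative=np.zeros(T),
            path_at_tfp=None,
            config=cfg,
        )

    def test_single_mode_gives_dimension_one(self):
        t = np.linspace(0, 10, 200)
        mode = np.outer(np.sin(t), np.ones(5))
        assert participation_ratio(self._traj_from_states(mode)) == pytest.approx(1.0)

    def test_equal_variance_modes_count_exactly(self, rng):
        # k orthogonal equal-variance modes, others silent -> PR = k
        k, N, T = 4, 12, 8000
        Q, _ = np.linalg.qr(rng.standard_normal((N, N)))
        coeffs = rng.standard_normal((T, k))
        X = coeffs @ Q[:, :k].T
        pr = participation_ratio(self._traj_from_states(X))
        assert pr == pytest.approx(k, rel=0.05)

    def test_converged_run_rejected_without_override(self, draw_weights):
        W = draw_weights(50, 0.0, geff=0.5, seed=1)
        traj = integrate(W, make_config(t_max=80.0, t_measure=80.0))
        assert traj.converged
        with pytest.raises(ParameterError):
            participation_ratio(traj)


class TestActivityStats:
    def test_quiescent_origin(self, zero_matrix):
        traj = integrate(zero_matrix, make_config(t_max=5.0, t_measure=5.0),
                         x0=np.zeros(10))
        st = activity_stats(traj, g=1.0)
        assert st.sigma == 0.0
        assert st.sigma_n == 0.0
        assert st.mean_sensitivity == 1.0

    def test_saturated_state_limits(self):
        # deeply saturated constant state: sensitivity -> 0, sigma_n -> g
        params = EnsembleParams(N=4, tau=0.0, g=2.0)
        X = np.full((10, 4), 30.0)
        traj = Trajectory(
            times=np.arange(10, dtype=float), states=X, derivs=np.zeros_like(X),
            converged=False, t_fp=None, path_cumulative=np.zeros(10),
            path_at_tfp=None, config=make_config(),
        )
        st = activity_stats(traj, g=2.0)
        assert st.mean_sensitivity == pytest.approx(0.0, abs=1e-12)
        assert st.sigma_n == pytest.approx(2.0, abs=1e-12)

    def test_noise_scale_approximates_activity_scale_in_chaos(self, draw_weights):
        W = draw_weights(500, 0.0, geff=1.4, seed=9)
        cfg = SimConfig(t_transient=100.0, t_measure=150.0, seed=9)
        traj = integrate(W, cfg)
        st = activity_stats(traj, W.params.g)
        assert abs(st.sigma_n - st.sigma) / st.sigma < 0.15


class TestPathLength:
    def test_linear_decay_closed_form(self, zero_matrix):
        # L = N^{-1/2} ||x0|| for pure exponential decay
        x0 = np.ones(10)  # ||x0|| = sqrt(10) = sqrt(N)
        traj = integrate(zero_matrix, make_config(t_max=60.0, t_measure=60.0), x0=x0)
        res = path_length(traj)
        assert not res.censored
        assert res.L == pytest.approx(1.0, abs=1e-3)

    def test_quadrature_converged_in_step_size(self, zero_matrix):
        x0 = np.ones(10)
        Ls = []
        for dt in (0.05, 0.025):
            cfg = SimConfig(dt=dt, t_transient=0.0, t_measure=60.0, t_max=60.0)
            Ls.append(path_length(integrate(zero_matrix, cfg, x0=x0)).L)
        assert abs(Ls[0] - Ls[1]) / Ls[1] < 1e-3

    def test_censoring_instead_of_exception(self, draw_weights):
        W = draw_weights(200, 0.0, geff=1.4, seed=3)
        traj = integrate(W, make_config(t_max=30.0, t_measure=30.0))
        res = path_length(traj)
        assert res.censored
        assert res.L is None and res.t_fp is None


class TestFixedPoints:
    def test_origin_always_found(self, draw_weights):
        W = draw_weights(20, 0.3, g=0.5, seed=2)
        fps = find_fixed_points(W, n_starts=20, start_radius=1.0, seed=0)
        assert any(np.linalg.norm(p) < 1e-8 for p in fps.points)
        assert all(r < 1e-10 for r in fps.residuals)

    def test_below_onset_origin_is_unique(self, draw_weights):
        W = draw_weights(50, 0.0, geff=0.8, seed=6)
        fps = find_fixed_points(W, n_starts=200, start_radius=2.0, seed=1)
        assert fps.n_distinct == 1

    def test_scalar_census_matches_exhaustive_count(self):
        from recnets import count_fixed_points_exhaustive

        params = EnsembleParams(N=1, tau=0.0, g=1.0)
        W = WeightMatrix(values=np.array([[1.5]]), params=params)
        fps = find_fixed_points(W, n_starts=50, start_radius=2.0, seed=0)
        assert fps.n_distinct == count_fixed_points_exhaustive(W) == 3
        # origin is unstable (slope w > 1), the outer pair is stable
        by_norm = sorted(zip(fps.points, fps.n_unstable_dims), key=lambda p: np.linalg.norm(p[0]))
        assert by_norm[0][1] == 1
        assert by_norm[1][1] == by_norm[2][1] == 0

    def test_symmetric_pair_structure(self, draw_weights):
        # odd activation: nonzero roots come in +/- pairs
        W = draw_weights(30, 0.5, geff=1.3, seed=11)
        fps = find_fixed_points(W, n_starts=100, start_radius=2.0, seed=2)
        nonzero = [p for p in fps.points if np.linalg.norm(p) > 1e-6]
        for p in nonzero:
            assert any(np.linalg.norm(p + q) < 1e-6 for q in nonzero)


class TestBatchedEnsemble:
    def test_matches_single_run_trajectory_observables(self, draw_weights):
        # same W, same seeds: batched engine reproduces per-run integrate
        W = draw_weights(100, 0.0, geff=1.3, seed=13)
        cfg = SimConfig(t_transient=20.0, t_measure=30.0, seed=5)
        res = simulate_ensemble([W], cfg)[0]
        traj = integrate(W, cfg)  # x0 seeding matches run index 0
        st = activity_stats(traj, W.params.g)
        assert res.sigma == pytest.approx(st.sigma, rel=1e-6)
        assert res.sigma_n == pytest.approx(st.sigma_n, rel=1e-6)
        assert res.mean_sensitivity == pytest.approx(st.mean_sensitivity, rel=1e-6)

    def test_matches_single_run_convergence_and_path(self, draw_weights):
        W = draw_weights(100, 0.0, geff=0.6, seed=14)
        cfg = SimConfig(t_transient=0.0, t_measure=100.0, t_max=100.0, seed=6)
        res = simulate_ensemble([W], cfg)[0]
        traj = integrate(W, cfg)
        pl = path_length(traj)
        assert res.converged and traj.converged
        assert res.t_fp == pytest.approx(traj.t_fp)
        assert res.path_length == pytest.approx(pl.L, rel=1e-9)

    def test_lyapunov_agrees_with_per_run_estimator(self, draw_weights):
        # contracting regime with convergence detection disabled: both
        # estimators track the same rightmost Jacobian eigenvalue
        W = draw_weights(200, 0.0, geff=0.5, seed=15)
        cfg = SimConfig(t_transient=20.0, t_measure=60.0, seed=7,
                        convergence_tol=1e-300)
        res = simulate_ensemble([W], cfg, with_tangent=True)[0]
        lam = lyapunov_max(W, cfg)
        assert res.lambda_max == pytest.approx(lam, abs=0.03)

    def test_mixed_convergence_bookkeeping(self, draw_weights):
        # one relaxing and one chaotic member in the same batch
        calm = draw_weights(100, 0.0, geff=0.5, seed=16)
        wild = draw_weights(100, 0.0, geff=1.5, seed=17)
        cfg = SimConfig(t_transient=0.0, t_measure=120.0, t_max=120.0, seed=8)
        res = simulate_ensemble([calm, wild], cfg)
        assert res[0].converged and res[0].path_length is not None
        assert not res[1].converged and res[1].censored
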