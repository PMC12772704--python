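"""Rate-network dynamics and dynamical observables.

The network state ``x in R^N`` (membrane potentials, time constant 1)
evolves as

    dx_i/dt = -x_i + sum_j w_ij S(x_j),       S(x) = tanh(x),

integrated with a fixed-step classical 4th-order Runge-Kutta scheme.  The
module computes every observable used to characterize the dynamics:

* maximal Lyapunov exponent (Benettin tangent-space method),
* participation-ratio dimensionality of the activity covariance,
* time-averaged activity standard deviation ``sigma``, mean-field noise
  ``sigma_n = g * sqrt(mean S(x)^2)`` and mean sensitivity ``mean S'(x)``,
* transient path length per neuron ``L = N^{-1/2} int_0^{t_fp} ||dx/dt|| dt``,
* damped-Newton fixed-point search with the analytic Jacobian
  ``J = -I + W diag(S'(x))``.

`simulate_ensemble` runs many independent realizations through the same
integrator simultaneously (batched matrix products); it is the engine
behind the parameter sweeps and agrees with the per-run functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .ensembles import ParameterError, WeightMatrix

__all__ = [
    "SimConfig",
    "Trajectory",
    "DynamicsObservables",
    "FixedPointSet",
    "ActivityStats",
    "PathLengthResult",
    "EnsembleRunResult",
    "integrate",
    "jacobian_at",
    "lyapunov_max",
    "participation_ratio",
    "activity_stats",
    "path_length",
    "find_fixed_points",
    "simulate_ensemble",
]

CONVERGENCE_STREAK = 5  # consecutive sub-threshold checks required


def _tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


def _tanh_prime(x: np.ndarray) -> np.ndarray:
    s = np.tanh(x)
    return 1.0 - s * s


@dataclass(frozen=True)
class SimConfig:
    """Integration and measurement settings (membrane time constant = 1).

    ``t_max`` defaults to ``t_transient + t_measure``.  The convergence
    criterion ``||dx/dt|| / sqrt(N) < convergence_tol``, checked every
    ``check_interval`` time units and required for 5 consecutive checks,
    is per-neuron normalized and hence N-independent; ``t_fp`` is the time
    of the first sub-threshold check.  Initial conditions are Gaussian with
    per-coordinate standard deviation ``x0_scale``.
    """

    dt: float = 0.05
    t_transient: float = 100.0
    t_measure: float = 1000.0
    t_max: float | None = None
    convergence_tol: float = 1e-9
    x0_scale: float = 1.0
    seed: int = 0
    t_renorm: float = 1.0
    check_interval: float = 1.0
    max_samples: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 < self.dt < 0.2:
            raise ParameterError("dt must lie in (0, 0.2) for stability")
        if self.t_transient < 0 or self.t_measure <= 0:
            raise ParameterError("t_transient >= 0 and t_measure > 0 required")
        if self.convergence_tol <= 0:
            raise ParameterError("convergence_tol must be positive")
        if self.t_max is not None and self.t_max <= 0:
            raise ParameterError("t_max must be positive")

    @property
    def total_time(self) -> float:
        return self.t_max if self.t_max is not None else self.t_transient + self.t_measure


@dataclass
class Trajectory:
    """Sampled trajectory with derivatives and convergence bookkeeping.

    ``derivs[k]`` is the vector field evaluated at ``states[k]``.
    ``path_cumulative[k]`` is the cumulative path integral
    ``int_0^{times[k]} ||dx/dt|| dt`` accumulated at full step resolution
    (not just at stored samples).  ``t_fp`` and ``path_at_tfp`` are present
    iff the run converged.
    """

    times: np.ndarray
    states: np.ndarray
    derivs: np.ndarray
    converged: bool
    t_fp: float | None
    path_cumulative: np.ndarray
    path_at_tfp: float | None
    config: SimConfig
    params: object | None = None


class ActivityStats(NamedTuple):
    sigma: float
    sigma_n: float
    mean_sensitivity: float


class PathLengthResult(NamedTuple):
    L: float | None
    t_fp: float | None
    censored: bool


@dataclass(frozen=True)
class DynamicsObservables:
    """Per-run bundle of dynamical observables (NaN/None where undefined)."""

    lambda_max: float | None = None
    participation_ratio: float | None = None
    sigma: float | None = None
    sigma_n: float | None = None
    mean_sensitivity: float | None = None
    path_length: float | None = None
    t_fp: float | None = None


def _x0_for(config: SimConfig, run_index: int, N: int) -> np.ndarray:
    ss = np.random.SeedSequence(config.seed, spawn_key=(int(run_index),))
    rng = np.random.default_rng(ss)
    return config.x0_scale * rng.standard_normal(N)


def _field(A: np.ndarray, x: np.ndarray) -> np.ndarray:
    return -x + A @ np.tanh(x)


def integrate(
    W: WeightMatrix, config: SimConfig, x0: np.ndarray | None = None
) -> Trajectory:
    """Integrate the rate network with fixed-step RK4.

    Runs until ``t_max`` (``t_transient + t_measure`` by default) or until
    convergence to a fixed point.  States and derivatives are stored with a
    stride chosen so at most ``config.max_samples`` samples are kept; the
    path integral ``int ||dx/dt|| dt`` is accumulated by the trapezoidal
    rule at every integration step regardless of the storage stride.
    """
    A = W.values
    N = A.shape[0]
    if x0 is None:
        x0 = _x0_for(config, 0, N)
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != (N,) or not np.all(np.isfinite(x)):
        raise ParameterError("x0 must be a finite N-vector")

    dt = config.dt
    n_steps = max(1, int(round(config.total_time / dt)))
    stride = max(1, math.ceil((n_steps + 1) / config.max_samples))
    m_check = max(1, int(round(config.check_interval / dt)))
    tol = config.convergence_tol
    sqrtN = math.sqrt(N)

    cur_f = _field(A, x)
    times = [0.0]
    states = [x.copy()]
    derivs = [cur_f.copy()]
    path_cum = [0.0]
    path = 0.0
    prev_speed = float(np.linalg.norm(cur_f))
    streak = 0
    t_fp: float | None = None
    path_at_tfp: float | None = None
    converged = False

    h2 = dt / 2.0
    for k in range(1, n_steps + 1):
        k1 = cur_f
        k2 = _field(A, x + h2 * k1)
        k3 = _field(A, x + h2 * k2)
        k4 = _field(A, x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        cur_f = _field(A, x)
        speed = float(np.linalg.norm(cur_f))
        if not math.isfinite(speed):
            raise FloatingPointError(
                f"non-finite state at t = {k * dt:.3f}; the tanh-bounded drive "
                "should prevent this - check dt and W"
            )
        path += 0.5 * dt * (prev_speed + speed)
        prev_speed = speed
        if k % stride == 0:
            times.append(k * dt)
            states.append(x.copy())
            derivs.append(cur_f.copy())
            path_cum.append(path)
        if k % m_check == 0:
            if speed / sqrtN < tol:
                streak += 1
                if streak == 1:
                    t_fp = k * dt
                    path_at_tfp = path
                if streak >= CONVERGENCE_STREAK:
                    converged = True
                    break
            else:
                streak = 0
                t_fp = None
                path_at_tfp = None
    if times[-1] != min(n_steps, k if converged else n_steps) * dt:
        times.append(k * dt if converged else n_steps * dt)
        states.append(x.copy())
        derivs.append(cur_f.copy())
        path_cum.append(path)

    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        derivs=np.asarray(derivs),
        converged=converged,
        t_fp=t_fp if converged else None,
        path_cumulative=np.asarray(path_cum),
        path_at_tfp=path_at_tfp if converged else None,
        config=config,
        params=W.params,
    )


def jacobian_at(W: WeightMatrix, x: np.ndarray) -> np.ndarray:
    """Jacobian ``J = -I + W diag(S'(x))`` of the rate dynamics at ``x``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("x must be finite")
    N = W.params.N
    return -np.eye(N) + W.values * _tanh_prime(x)[None, :]


def lyapunov_max(
    W: WeightMatrix, config: SimConfig, x0: np.ndarray | None = None
) -> float:
    """Maximal Lyapunov exponent by the Benettin tangent-space method.

    One tangent vector is co-integrated under ``dv/dt = J(x(t)) v`` (the
    tangent RK4 stages use the matching state stages), renormalized every
    ``t_renorm`` time units with the log stretch factors accumulated over
    the measurement window; the transient is discarded.  Using the exact
    tangent flow avoids the nonlinearity contamination of finite trajectory
    separations.
    """
    A = W.values
    N = A.shape[0]
    if x0 is None:
        x0 = _x0_for(config, 0, N)
    x = np.asarray(x0, dtype=float).copy()
    dt = config.dt
    h2 = dt / 2.0
    n_tr = int(round(config.t_transient / dt))
    n_meas = int(round(config.t_measure / dt))
    m_renorm = max(1, int(round(config.t_renorm / dt)))

    def step(x: np.ndarray) -> np.ndarray:
        k1 = _field(A, x)
        k2 = _field(A, x + h2 * k1)
        k3 = _field(A, x + h2 * k2)
        k4 = _field(A, x + dt * k3)
        return x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    for _ in range(n_tr):
        x = step(x)

    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0, 1))
    )
    v = rng.standard_normal(N)
    v /= np.linalg.norm(v)

    def tangent(xs: np.ndarray, vs: np.ndarray) -> np.ndarray:
        return -vs + A @ (_tanh_prime(xs) * vs)

    log_sum = 0.0
    for k in range(1, n_meas + 1):
        k1 = _field(A, x)
        l1 = tangent(x, v)
        x2 = x + h2 * k1
        k2 = _field(A, x2)
        l2 = tangent(x2, v + h2 * l1)
        x3 = x + h2 * k2
        k3 = _field(A, x3)
        l3 = tangent(x3, v + h2 * l2)
        x4 = x + dt * k3
        k4 = _field(A, x4)
        l4 = tangent(x4, v + dt * l3)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        v = v + (dt / 6.0) * (l1 + 2.0 * l2 + 2.0 * l3 + l4)
        if k % m_renorm == 0:
            r = float(np.linalg.norm(v))
            if r == 0.0:
                raise FloatingPointError("tangent vector collapsed to zero")
            log_sum += math.log(r)
            v /= r
    r = float(np.linalg.norm(v))
    if r > 0 and n_meas % m_renorm != 0:
        log_sum += math.log(r)
    return log_sum / (n_meas * dt)


def _measurement_mask(traj: Trajectory) -> np.ndarray:
    return traj.times >= traj.config.t_transient


def participation_ratio(traj: Trajectory, allow_converged: bool = False) -> float:
    """Participation-ratio dimensionality of the activity covariance.

    ``PR = (sum mu_i)^2 / sum mu_i^2`` over the eigenvalues ``mu_i`` of the
    time covariance of the states in the measurement window, mean-subtracted
    per neuron.  Lies in ``[1, N]``.  Raises on converged runs (the
    covariance degenerates at a fixed point) unless ``allow_converged``.
    """
    if traj.converged and not allow_converged:
        raise ParameterError(
            "participation ratio is undefined for a converged run "
            "(pass allow_converged=True to override)"
        )
    X = traj.states[_measurement_mask(traj)]
    if X.shape[0] < 2:
        raise ParameterError("measurement window holds fewer than 2 samples")
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    mu = sv * sv
    total = float(mu.sum())
    if total <= 0.0:
        raise ParameterError("degenerate trajectory: zero total variance")
    return float(total * total / np.sum(mu * mu))


def activity_stats(traj: Trajectory, g: float) -> ActivityStats:
    """Time-averaged activity scale, mean-field noise scale, and sensitivity.

    Per stored sample: ``sigma(t) = sqrt(mean_j x_j^2)``,
    ``sigma_n(t) = g * sqrt(mean_j S(x_j)^2)`` and mean sensitivity
    ``mean_j S'(x_j)``; each is then averaged over the measurement window.
    """
    mask = _measurement_mask(traj)
    X = traj.states[mask]
    if X.shape[0] == 0:
        raise ParameterError("measurement window is empty")
    S = np.tanh(X)
    sigma = float(np.mean(np.sqrt(np.mean(X * X, axis=1))))
    sigma_n = float(g * np.mean(np.sqrt(np.mean(S * S, axis=1))))
    sens = float(np.mean(1.0 - S * S))
    return ActivityStats(sigma=sigma, sigma_n=sigma_n, mean_sensitivity=sens)


def path_length(traj: Trajectory) -> PathLengthResult:
    """Transient path length per neuron, ``L = N^{-1/2} int_0^{t_fp} ||dx/dt|| dt``.

    The integral is the trapezoidal accumulation recorded at every
    integration step.  Non-convergent runs are censored: ``L`` and ``t_fp``
    are absent and ``censored`` is set, rather than raising.
    """
    if not traj.converged:
        return PathLengthResult(L=None, t_fp=None, censored=True)
    N = traj.states.shape[1]
    return PathLengthResult(
        L=traj.path_at_tfp / math.sqrt(N), t_fp=traj.t_fp, censored=False
    )


# ---------------------------------------------------------------------------
# fixed-point search
# ---------------------------------------------------------------------------


@dataclass
class FixedPointSet:
    """Deduplicated fixed points with residuals and local stability counts."""

    points: list[np.ndarray]
    residuals: list[float]
    n_unstable_dims: list[int]
    n_distinct: int
    n_failed_starts: int = 0


def _newton_root(
    A: np.ndarray,
    x0: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray | None:
    """Damped Newton on F(x) = -x + A tanh(x); None if not converged."""
    N = A.shape[0]
    x = np.asarray(x0, dtype=float).copy()
    F = -x + A @ np.tanh(x)
    fn = float(np.linalg.norm(F, np.inf))
    for _ in range(max_iter):
        if fn < tol:
            return x
        J = -np.eye(N) + A * _tanh_prime(x)[None, :]
        try:
            d = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            d, *_ = np.linalg.lstsq(J, -F, rcond=None)
        lam = 1.0
        for _ in range(40):
            x_new = x + lam * d
            F_new = -x_new + A @ np.tanh(x_new)
            fn_new = float(np.linalg.norm(F_new, np.inf))
            if fn_new < fn:
                break
            lam *= 0.5
        else:
            return None
        x, F, fn = x_new, F_new, fn_new
        if np.linalg.norm(x) > 1e8:
            return None
    return x if fn < tol else None


def find_fixed_points(
    W: WeightMatrix,
    n_starts: int = 100,
    start_radius: float = 1.0,
    seed: int = 0,
    dedupe_tol: float = 1e-6,
    residual_tol: float = 1e-10,
) -> FixedPointSet:
    """Newton census of fixed points from random Gaussian initial points.

    Damped Newton iterations with the analytic Jacobian start from
    ``n_starts`` points with per-coordinate standard deviation
    ``start_radius`` (the origin, always a fixed point of the odd dynamics,
    is seeded explicitly).  Converged roots are deduplicated by Euclidean
    distance; the sign symmetry ``x* <-> -x*`` of the odd activation is
    exploited to complete the census.  Every reported root satisfies
    ``||F(x*)||_inf < residual_tol``; each root's number of unstable
    directions comes from the eigenvalues of the Jacobian.
    """
    A = W.values
    N = A.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    starts = [np.zeros(N)]
    starts.extend(
        start_radius * rng.standard_normal(N) for _ in range(n_starts)
    )
    roots: list[np.ndarray] = []
    n_failed = 0
    for x0 in starts:
        root = _newton_root(A, x0)
        if root is None:
            n_failed += 1
            continue
        for cand in (root, -root):  # odd activation: roots come in +/- pairs
            resid = float(np.linalg.norm(-cand + A @ np.tanh(cand), np.inf))
            if resid >= residual_tol:
                continue
            if not any(np.linalg.norm(cand - r) < dedupe_tol for r in roots):
                roots.append(cand.copy())
    residuals = [
        float(np.linalg.norm(-r + A @ np.tanh(r), np.inf)) for r in roots
    ]
    unstable = []
    for r in roots:
        J = -np.eye(N) + A * _tanh_prime(r)[None, :]
        ev = np.linalg.eigvals(J)
        unstable.append(int(np.sum(ev.real > 0.0)))
    return FixedPointSet(
        points=roots,
        residuals=residuals,
        n_unstable_dims=unstable,
        n_distinct=len(roots),
        n_failed_starts=n_failed,
    )


# ---------------------------------------------------------------------------
# batched ensemble simulation (engine behind the sweeps)
# ---------------------------------------------------------------------------


@dataclass
class EnsembleRunResult:
    """Observables of one run of a batched ensemble simulation."""

    run_index: int
    converged: bool
    t_fp: float | None
    path_length: float | None
    censored: bool
    sigma: float | None
    sigma_n: float | None
    mean_sensitivity: float | None
    lambda_max: float | None
    participation_ratio: float | None


def simulate_ensemble(
    Ws: Sequence[WeightMatrix],
    config: SimConfig,
    with_tangent: bool = False,
    store_states: bool = False,
    pr_max_samples: int = 500,
) -> list[EnsembleRunResult]:
    """Run many independent realizations through one batched integrator.

    All matrices must share the network size.  Each run gets its own
    initial condition (seeded by run index from ``config.seed``), its own
    convergence detection, path-length accumulator and, optionally, its own
    Benettin tangent vector (``with_tangent``) and strided state storage for
    the participation ratio (``store_states``).  Converged runs are removed
    from the batch, so ensembles whose members relax early cost little.

    The arithmetic per run is the same RK4/tangent scheme as the per-run
    functions; results agree with them up to floating-point reduction order.
    """
    M = len(Ws)
    if M == 0:
        raise ParameterError("need at least one weight matrix")
    N = Ws[0].params.N
    for w in Ws:
        if w.params.N != N:
            raise ParameterError("all matrices must share the network size N")
    gs = np.array([w.params.g for w in Ws])
    A = np.stack([w.values for w in Ws])  # (M, N, N)
    X = np.stack([_x0_for(config, i, N) for i in range(M)])

    dt = config.dt
    h2 = dt / 2.0
    n_steps = max(1, int(round(config.total_time / dt)))
    m_check = max(1, int(round(config.check_interval / dt)))
    m_renorm = max(1, int(round(config.t_renorm / dt)))
    tol = config.convergence_tol
    sqrtN = math.sqrt(N)

    if with_tangent:
        V = np.empty_like(X)
        for i in range(M):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(i, 1))
            )
            v = rng.standard_normal(N)
            V[i] = v / np.linalg.norm(v)
    else:
        V = None

    store_stride = max(1, math.ceil(n_steps / pr_max_samples)) if store_states else 0
    stored: dict[int, list[np.ndarray]] = {i: [] for i in range(M)} if store_states else {}

    # per-run accumulators, indexed by original run index
    path = np.zeros(M)
    prev_speed = np.zeros(M)
    streak = np.zeros(M, dtype=int)
    t_fp = np.full(M, np.nan)
    path_at_tfp = np.full(M, np.nan)
    converged = np.zeros(M, dtype=bool)
    log_sum = np.zeros(M)
    sum_sigma = np.zeros(M)
    sum_sigma_n = np.zeros(M)
    sum_sens = np.zeros(M)
    n_meas = np.zeros(M, dtype=int)

    def batch_field(Ab: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        return -Xb + np.matmul(Ab, np.tanh(Xb)[..., None])[..., 0]

    def batch_tangent(Ab: np.ndarray, Xb: np.ndarray, Vb: np.ndarray) -> np.ndarray:
        return -Vb + np.matmul(Ab, (_tanh_prime(Xb) * Vb)[..., None])[..., 0]

    active = np.arange(M)
    Ab, Xb = A, X
    Vb = V
    Fb = batch_field(Ab, Xb)
    prev_speed[active] = np.linalg.norm(Fb, axis=1)

    for k in range(1, n_steps + 1):
        t = k * dt
        k1 = Fb
        if with_tangent:
            l1 = batch_tangent(Ab, Xb, Vb)
        X2 = Xb + h2 * k1
        k2 = batch_field(Ab, X2)
        if with_tangent:
            l2 = batch_tangent(Ab, X2, Vb + h2 * l1)
        X3 = Xb + h2 * k2
        k3 = batch_field(Ab, X3)
        if with_tangent:
            l3 = batch_tangent(Ab, X3, Vb + h2 * l2)
        X4 = Xb + dt * k3
        k4 = batch_field(Ab, X4)
        if with_tangent:
            l4 = batch_tangent(Ab, X4, Vb + dt * l3)
        Xb = Xb + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if with_tangent:
            Vb = Vb + (dt / 6.0) * (l1 + 2.0 * l2 + 2.0 * l3 + l4)
        Fb = batch_field(Ab, Xb)
        speed = np.linalg.norm(Fb, axis=1)
        if not np.all(np.isfinite(speed)):
            raise FloatingPointError("non-finite state in batched integration")
        path[active] += 0.5 * dt * (prev_speed[active] + speed)
        prev_speed[active] = speed

        if with_tangent and k % m_renorm == 0:
            r = np.linalg.norm(Vb, axis=1)
            if t > config.t_transient:
                log_sum[active] += np.log(r)
            Vb = Vb / r[:, None]

        if t >= config.t_transient:
            Sb = np.tanh(Xb)
            sum_sigma[active] += np.sqrt(np.mean(Xb * Xb, axis=1))
            sum_sigma_n[active] += np.sqrt(np.mean(Sb * Sb, axis=1))
            sum_sens[active] += np.mean(1.0 - Sb * Sb, axis=1)
            n_meas[active] += 1

        if store_states and k % store_stride == 0:
            for j, i in enumerate(active):
                stored[i].append(Xb[j].copy())

        if k % m_check == 0:
            below = speed / sqrtN < tol
            idx = active
            newly_first = below & (streak[idx] == 0)
            streak[idx] = np.where(below, streak[idx] + 1, 0)
            first = idx[newly_first]
            t_fp[first] = t
            path_at_tfp[first] = path[first]
            reset = idx[~below]
            t_fp[reset] = np.nan
            path_at_tfp[reset] = np.nan
            done = streak[idx] >= CONVERGENCE_STREAK
            if np.any(done):
                converged[idx[done]] = True
                keep = ~done
                active = idx[keep]
                if active.size == 0:
                    break
                Ab = Ab[keep]
                Xb = Xb[keep]
                Fb = Fb[keep]
                if with_tangent:
                    Vb = Vb[keep]

    results: list[EnsembleRunResult] = []
    t_measure_eff = config.total_time - config.t_transient
    for i in range(M):
        conv = bool(converged[i])
        L = path_at_tfp[i] / sqrtN if conv else None
        if n_meas[i] > 0:
            sigma = float(sum_sigma[i] / n_meas[i])
            sigma_n = float(gs[i] * sum_sigma_n[i] / n_meas[i])
            sens = float(sum_sens[i] / n_meas[i])
        else:
            sigma = sigma_n = sens = None
        lam = float(log_sum[i] / t_measure_eff) if (with_tangent and not conv) else None
        pr = None
        if store_states and not conv and len(stored[i]) >= 2:
            Xs = np.asarray(stored[i])
            Xs = Xs - Xs.mean(axis=0)
            sv = np.linalg.svd(Xs, compute_uv=False)
            mu = sv * sv
            tot = float(mu.sum())
            if tot > 0:
                pr = float(tot * tot / np.sum(mu * mu))
        results.append(
            EnsembleRunResult(
                run_index=i,
                converged=conv,
                t_fp=float(t_fp[i]) if conv else None,
                path_length=float(L) if L is not None else None,
                censored=not conv,
                sigma=sigma,
                sigma_n=sigma_n,
                mean_sensitivity=sens,
                lambda_max=lam,
                participation_ratio=pr,
            )
        )
    return results
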