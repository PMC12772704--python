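"""Topological complexity of partially symmetric random rate networks.

The topological complexity

    c(g, tau) = lim_{N -> inf} (1/N) log E[ A_N(g, tau) ]

is the exponential growth rate, with network size, of the expected number
of fixed points ``A_N`` of the rate dynamics.  Below the instability onset
of the quiescent state (effective gain ``geff = g (1 + tau) < 1``) the
origin is the unique fixed point and ``c = 0``.  Above onset a Kac-Rice
computation reduces the annealed count to an expected absolute determinant,
whose ``N -> inf`` limit is the log-potential of the elliptic law at 1,
giving the closed form

    c(g, tau) = 1 / (2 g^2 (1 + tau)) - 1/2 + log g
              = (1 + tau) / (2 geff^2) - 1/2 + log geff - log(1 + tau).

Near onset (``geff = 1 + eps``) the second-order expansion

    c ~= -eps * tau + eps^2 (3 tau / 2 + 1) + tau/2 - log(1 + tau)

shows the two regimes: for ``tau < 0`` the complexity turns on linearly in
``eps`` (first-order transition) while at ``tau = 0`` it grows as ``eps^2``.
For ``tau`` slightly positive the leading-order expression is negative near
onset (the exponential estimate then says nothing about subexponentially
many fixed points), and it crosses zero at ``tau* ~= 2 eps^2``.  As
``tau -> -1`` the complexity diverges.

A small-``N`` Monte-Carlo estimator of ``(1/N) log E|det(-I + W)|`` and a
brute-force fixed-point counter for ``N <= 3`` provide finite-size checks
of the annealed picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .ensembles import (
    EnsembleParams,
    ParameterError,
    WeightMatrix,
    resolve_gain,
    sample_weights,
)

__all__ = [
    "ComplexityDivergenceError",
    "NoSignChangeError",
    "ComplexityValue",
    "KacRiceEstimate",
    "complexity_closed_form",
    "onset_expansion",
    "sign_change_tau",
    "kac_rice_mc",
    "count_fixed_points_exhaustive",
]


class ComplexityDivergenceError(ValueError):
    """Raised at tau = -1, where the topological complexity diverges."""


class NoSignChangeError(ValueError):
    """Raised when c(geff, .) has no zero crossing in (0, 1]."""


@dataclass(frozen=True)
class ComplexityValue:
    """Complexity at one parameter point, with regime bookkeeping.

    ``c_raw`` is the analytic expression; ``c`` is the regime-aware value
    (0 below onset, ``c_raw`` at or above onset); ``c_contribution`` is
    ``max(0, c)``, the part that actually contributes to the exponential
    scaling of the expected fixed-point count.
    """

    c_raw: float
    c: float
    c_contribution: float
    g: float
    geff: float
    tau: float
    below_onset: bool


@dataclass(frozen=True)
class KacRiceEstimate:
    """Monte-Carlo estimate of (1/N) log E|det(-I + W)|."""

    N: int
    M: int
    log_mean_absdet_per_N: float
    stderr: float
    g: float
    tau: float
    seed: int

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ParameterError("need at least M = 2 realizations")
        if self.stderr < 0:
            raise ParameterError("stderr must be non-negative")


def complexity_closed_form(
    g: float | None = None, tau: float = 0.0, geff: float | None = None
) -> ComplexityValue:
    """Closed-form topological complexity at ``(g, tau)`` or ``(geff, tau)``.

    Either parameterization resolves to the same effective gain first and
    evaluates one expression, so the two routes agree bit-for-bit.  Raises
    :class:`ComplexityDivergenceError` at ``tau = -1``.
    """
    if tau == -1.0:
        raise ComplexityDivergenceError(
            "topological complexity diverges as tau -> -1"
        )
    g, geff = resolve_gain(g, geff, tau)
    c_raw = (1.0 + tau) / (2.0 * geff * geff) - 0.5 + math.log(geff) - math.log1p(tau)
    below = geff < 1.0
    c = 0.0 if below else c_raw
    return ComplexityValue(
        c_raw=c_raw,
        c=c,
        c_contribution=max(0.0, c),
        g=g,
        geff=geff,
        tau=tau,
        below_onset=below,
    )


def onset_expansion(geff: float, tau: float) -> float:
    """Second-order expansion of the complexity in ``geff - 1`` near onset.

    ``c ~= -(geff-1) tau + (geff-1)^2 (3 tau/2 + 1) + tau/2 - log(1+tau)``.
    """
    if tau == -1.0:
        raise ComplexityDivergenceError(
            "topological complexity diverges as tau -> -1"
        )
    if not -1.0 < tau <= 1.0:
        raise ParameterError(f"tau must lie in (-1, 1], got {tau}")
    eps = geff - 1.0
    return -eps * tau + eps * eps * (1.5 * tau + 1.0) + tau / 2.0 - math.log1p(tau)


def sign_change_tau(geff: float, xtol: float = 1e-10) -> float:
    """Root ``tau* in (0, 1]`` of ``c_raw(geff, tau) = 0``.

    Above onset the raw complexity is positive at ``tau = 0`` and, for
    ``geff`` near 1, turns negative at ``tau* ~= 2 (geff - 1)^2``.  Found by
    bracketed bisection (``brentq``) after a coarse scan; raises
    :class:`NoSignChangeError` when no crossing exists (large ``geff``).
    """
    if not geff > 1.0:
        raise ParameterError("sign_change_tau requires geff > 1")

    def f(tau: float) -> float:
        return complexity_closed_form(geff=geff, tau=tau).c_raw

    lo = 0.0
    f_lo = f(lo)
    if f_lo <= 0.0:  # pragma: no cover - cannot happen for geff > 1
        raise NoSignChangeError("c_raw is not positive at tau = 0")
    # Coarse geometric-then-linear scan for a bracket.
    grid = np.concatenate([np.geomspace(1e-8, 1.0, 200)])
    hi = None
    for t in grid:
        if f(t) < 0.0:
            hi = t
            break
        lo = t
    if hi is None:
        raise NoSignChangeError(
            f"c_raw(geff={geff}, tau) has no sign change in (0, 1]"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def kac_rice_mc(
    N: int, g: float, tau: float, M: int, seed: int = 0
) -> KacRiceEstimate:
    """Monte-Carlo estimate of ``(1/N) log E|det(-I + W)|`` over ``M`` draws.

    The annealed mean of ``|det|`` is heavy-tailed (dominated by rare
    draws), so the estimator is restricted to small ``N`` and accumulates in
    the log domain (log-sum-exp of sign-magnitude log-determinants).  The
    standard error on the log-mean comes from the delta method.
    """
    if N > 100:
        raise ParameterError(
            "kac_rice_mc is limited to N <= 100: the annealed |det| average "
            "is dominated by rare draws and its MC variance explodes with N"
        )
    if M < 100:
        raise ParameterError("need M >= 100 realizations")
    params = EnsembleParams(N=N, tau=tau, g=g, seed=seed)
    I = np.eye(N)
    logdets = np.empty(M)
    for m in range(M):
        W = sample_weights(params, realization_index=m)
        _, logabs = np.linalg.slogdet(-I + W.values)
        logdets[m] = logabs
    log_mean = float(logsumexp(logdets) - math.log(M))
    # Delta method: Var(log mean) ~= Var(X) / (M * mean(X)^2), computed
    # stably on ratios exp(l - log_mean).
    ratios = np.exp(logdets - log_mean)
    stderr = float(np.std(ratios, ddof=1) / math.sqrt(M))
    return KacRiceEstimate(
        N=N,
        M=M,
        log_mean_absdet_per_N=log_mean / N,
        stderr=stderr / N,
        g=float(g),
        tau=float(tau),
        seed=int(seed),
    )


def _fixed_point_count_1d(w: float, n_grid: int = 4001) -> int:
    """Count roots of x = w * tanh(x) by dense sign-change bracketing."""
    bound = abs(w) + 1.0
    xs = np.linspace(-bound, bound, n_grid)
    f = -xs + w * np.tanh(xs)
    roots: list[float] = []
    for k in range(len(xs) - 1):
        a, b = f[k], f[k + 1]
        if a == 0.0:
            roots.append(xs[k])
        elif a * b < 0.0:
            roots.append(float(brentq(lambda x: -x + w * math.tanh(x), xs[k], xs[k + 1])))
    if f[-1] == 0.0:
        roots.append(xs[-1])
    dedup: list[float] = []
    for r in sorted(roots):
        if not dedup or abs(r - dedup[-1]) > 1e-8:
            dedup.append(r)
    return len(dedup)


def count_fixed_points_exhaustive(W: WeightMatrix) -> int:
    """Count all fixed points ``-x + W tanh(x) = 0`` for ``N <= 3``.

    ``N = 1`` uses dense sign-change bracketing with root refinement (the
    scalar equation ``x = w tanh x`` has 1 root for ``w <= 1`` and 3 for
    ``w > 1``).  ``N in {2, 3}`` seeds damped Newton iterations from a dense
    grid covering the invariant box ``|x_i| <= sum_j |w_ij|`` and
    deduplicates the converged roots.
    """
    N = W.params.N
    if N > 3:
        raise ParameterError(
            "exhaustive counting is limited to N <= 3; use "
            "dynamics.find_fixed_points for a Newton census at larger N"
        )
    v = W.values
    if N == 1:
        return _fixed_point_count_1d(float(v[0, 0]))

    from .dynamics import _newton_root  # local import to avoid a cycle

    bounds = np.abs(v).sum(axis=1) + 0.5
    n_per_dim = 21 if N == 2 else 11
    axes = [np.linspace(-b, b, n_per_dim) for b in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    starts = np.stack([m.ravel() for m in mesh], axis=1)
    roots: list[np.ndarray] = []
    for x0 in starts:
        root = _newton_root(v, x0)
        if root is None:
            continue
        if not any(np.linalg.norm(root - r) < 1e-6 for r in roots):
            roots.append(root)
    return len(roots)
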