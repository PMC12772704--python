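"""Gaussian connectivity ensembles with correlated reciprocal weights.

A network of ``N`` rate units is coupled through an ``N x N`` Gaussian
weight matrix ``W`` with zero mean and covariance

    <w_ij w_kl> = (g^2 / N) * (delta_ik delta_jl + tau * delta_il delta_jk),

so that every reciprocal pair ``(w_ij, w_ji)`` (``i != j``) is bivariate
Gaussian with marginal variance ``g^2/N`` and correlation ``tau``, while
distinct unordered pairs are independent.  ``tau = 1`` forces an exactly
symmetric matrix, ``tau = -1`` an exactly antisymmetric one, and ``tau = 0``
recovers the classical i.i.d. (Ginibre-like) ensemble.

The sampler realizes this law pairwise:

    w_ij = (g / sqrt(N)) * (alpha * z_ij + beta * z_ji),

with independent standard normals ``z`` and mixing coefficients

    alpha = (sqrt(1 + tau) + sqrt(1 - tau)) / 2,
    beta  = (sqrt(1 + tau) - sqrt(1 - tau)) / 2,

which satisfy ``alpha^2 + beta^2 = 1`` and ``2 * alpha * beta = tau``.  The
pairwise form makes the joint law of each reciprocal pair transparent and
directly testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "EnsembleParams",
    "WeightMatrix",
    "PairStats",
    "resolve_gain",
    "mixing_coefficients",
    "sample_weights",
    "pair_statistics",
    "symmetry_split",
]

DIAGONAL_POLICIES = ("correlated_gaussian", "zero")


class ParameterError(ValueError):
    """Raised for invalid ensemble parameters."""


def resolve_gain(
    g: float | None, geff: float | None, tau: float
) -> tuple[float, float]:
    """Resolve the (gain, effective gain) pair from exactly one of them.

    The effective gain ``geff = g * (1 + tau)`` is the rightmost extent of
    the limiting spectrum; ``geff = 1`` marks the instability onset of the
    quiescent state.  Supplying ``geff`` at ``tau = -1`` is rejected: the
    map to ``g`` degenerates there.
    """
    if not -1.0 <= tau <= 1.0:
        raise ParameterError(f"tau must lie in [-1, 1], got {tau}")
    if (g is None) == (geff is None):
        raise ParameterError("exactly one of g and geff must be supplied")
    if g is None:
        if tau == -1.0:
            raise ParameterError(
                "geff cannot be specified at tau = -1: g = geff/(1+tau) is undefined"
            )
        g = geff / (1.0 + tau)
    else:
        geff = g * (1.0 + tau)
    if not g > 0.0:
        raise ParameterError(f"gain g must be positive, got {g}")
    return float(g), float(geff)


@dataclass(frozen=True)
class EnsembleParams:
    """Generative specification of one connectivity draw.

    Exactly one of ``g`` (coupling gain) and ``geff`` (effective gain,
    ``g * (1 + tau)``) must be supplied; the other is derived.

    Parameters
    ----------
    N : int
        Network size (number of units), ``N >= 1``.
    tau : float
        Reciprocal correlation in ``[-1, 1]``.
    g, geff : float, optional
        Coupling gain / effective gain; supply exactly one.
    seed : int
        Root seed; together with ``realization_index`` it determines the
        draw bit-for-bit.
    diagonal_policy : {"correlated_gaussian", "zero"}
        The covariance display evaluated at ``i = j`` gives
        ``Var(w_ii) = g^2 (1 + tau) / N``; ``correlated_gaussian`` (default)
        follows that literally, ``zero`` zeroes the diagonal.
    """

    N: int
    tau: float
    g: float | None = None
    geff: float | None = None
    seed: int = 0
    diagonal_policy: str = "correlated_gaussian"

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ParameterError(f"N must be a positive integer, got {self.N}")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ParameterError(f"seed must be a non-negative integer, got {self.seed}")
        if self.diagonal_policy not in DIAGONAL_POLICIES:
            raise ParameterError(
                f"diagonal_policy must be one of {DIAGONAL_POLICIES}, "
                f"got {self.diagonal_policy!r}"
            )
        g, geff = resolve_gain(self.g, self.geff, self.tau)
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "tau", float(self.tau))
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "geff", geff)
        object.__setattr__(self, "seed", int(self.seed))


@dataclass(frozen=True)
class WeightMatrix:
    """One realization of the connectivity matrix with its provenance."""

    values: np.ndarray
    params: EnsembleParams
    realization_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.params.N, self.params.N):
            raise ParameterError(
                f"values must be {self.params.N}x{self.params.N}, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ParameterError("weight matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def N(self) -> int:
        return self.params.N


@dataclass(frozen=True)
class PairStats:
    """Pooled empirical second moments of reciprocal weight pairs.

    ``degenerate`` is set (and ``reciprocal_corr`` is NaN) when the pooled
    off-diagonal variance vanishes, so a correlation is undefined.
    """

    mean: float
    var_offdiag: float
    reciprocal_corr: float
    n_pairs: int
    stderr_var: float
    stderr_corr: float
    degenerate: bool = False


def mixing_coefficients(tau: float) -> tuple[float, float]:
    """Pairwise mixing coefficients (alpha, beta) for correlation ``tau``."""
    alpha = (math.sqrt(1.0 + tau) + math.sqrt(1.0 - tau)) / 2.0
    beta = (math.sqrt(1.0 + tau) - math.sqrt(1.0 - tau)) / 2.0
    return alpha, beta


def _rng_for(params: EnsembleParams, realization_index: int) -> np.random.Generator:
    # Counter-based spawning: one root seed, independent per-realization
    # streams, so sweeps are reproducible without coordination.
    ss = np.random.SeedSequence(params.seed, spawn_key=(int(realization_index),))
    return np.random.default_rng(ss)


def sample_weights(params: EnsembleParams, realization_index: int = 0) -> WeightMatrix:
    """Sample one weight matrix with the prescribed reciprocal correlation.

    For ``i != j`` the pair ``(w_ij, w_ji)`` is bivariate Gaussian with zero
    mean, marginal variance ``g^2/N`` and correlation ``tau``; distinct
    unordered pairs are independent.  At ``tau = 1`` the matrix is exactly
    symmetric, at ``tau = -1`` exactly antisymmetric with a zero diagonal.
    Deterministic given ``(params.seed, realization_index)``.
    """
    N, g, tau = params.N, params.g, params.tau
    alpha, beta = mixing_coefficients(tau)
    rng = _rng_for(params, realization_index)
    Z = rng.standard_normal((N, N))
    W = (g / math.sqrt(N)) * (alpha * Z + beta * Z.T)
    if params.diagonal_policy == "zero":
        np.fill_diagonal(W, 0.0)
    # correlated_gaussian diagonal falls out of the same blend:
    # w_ii = (g/sqrt(N)) (alpha+beta) z_ii with variance g^2 (1+tau)/N.
    return WeightMatrix(values=W, params=params, realization_index=realization_index)


def pair_statistics(matrices: Sequence[WeightMatrix]) -> PairStats:
    """Pooled empirical moments of ``(w_ij, w_ji)`` over realizations.

    Pools all unordered off-diagonal pairs from every matrix (all matrices
    must share identical parameters) and returns the empirical mean and
    variance of the off-diagonal entries, the Pearson correlation between
    reciprocal partners, and delta-method standard errors.
    """
    if len(matrices) == 0:
        raise ParameterError("need at least one matrix")
    params = matrices[0].params
    for m in matrices[1:]:
        if m.params != params:
            raise ParameterError("all matrices must share identical EnsembleParams")
    N = params.N
    if N < 2:
        raise ParameterError("pair statistics require N >= 2")
    iu = np.triu_indices(N, k=1)
    upper = np.concatenate([m.values[iu] for m in matrices])
    lower = np.concatenate([m.values.T[iu] for m in matrices])
    offdiag = np.concatenate([upper, lower])
    n_pairs = upper.size
    mean = float(offdiag.mean())
    var = float(offdiag.var(ddof=1))
    if var <= 0.0:
        return PairStats(
            mean=mean,
            var_offdiag=var,
            reciprocal_corr=float("nan"),
            n_pairs=n_pairs,
            stderr_var=0.0,
            stderr_corr=float("nan"),
            degenerate=True,
        )
    corr = float(np.corrcoef(upper, lower)[0, 1])
    # SE of the pooled variance: entries are Gaussian but reciprocal partners
    # are correlated, inflating the variance of the variance by (1 + corr^2).
    stderr_var = var * math.sqrt(2.0 * (1.0 + corr**2) / offdiag.size)
    stderr_corr = (1.0 - corr**2) / math.sqrt(n_pairs)
    return PairStats(
        mean=mean,
        var_offdiag=var,
        reciprocal_corr=corr,
        n_pairs=n_pairs,
        stderr_var=stderr_var,
        stderr_corr=stderr_corr,
        degenerate=False,
    )


def symmetry_split(W: WeightMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split ``W`` into symmetric and antisymmetric parts, ``W = S + A``
    (up to floating-point rounding)."""
    v = W.values if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    S = (v + v.T) / 2.0
    A = (v - v.T) / 2.0
    return S, A
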