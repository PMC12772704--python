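"""Spectra of correlated Gaussian matrices and the limiting elliptic law.

As ``N -> infinity`` the eigenvalues of a weight matrix with reciprocal
correlation ``tau`` fill, uniformly, the ellipse with semi-axes
``a = g (1 + tau)`` along the real axis and ``b = g (1 - tau)`` along the
imaginary axis.  ``tau = 0`` gives the circular law on the disk of radius
``g``; ``tau = 1`` collapses the support onto the segment ``[-2g, 2g]``
(whose marginal is Wigner's semicircle); ``tau = -1`` collapses it onto the
imaginary segment ``[-2ig, 2ig]``.

This module also provides the logarithmic potential of the uniform ellipse
measure, evaluated by adaptive quadrature.  At ``w = 1`` that potential is
the annealed fixed-point growth rate of the network, so the quadrature
serves as an independent numerical oracle for the closed-form complexity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .ensembles import EnsembleParams, ParameterError, WeightMatrix, resolve_gain

__all__ = [
    "EllipseSpec",
    "Spectrum",
    "ellipse_axes",
    "eigenvalues",
    "spectrum_support_check",
    "log_potential",
]


@dataclass(frozen=True)
class EllipseSpec:
    """Limiting spectral support: uniform measure on an ellipse.

    Semi-axes ``a = g (1 + tau)`` (real direction) and ``b = g (1 - tau)``
    (imaginary direction); total mass 1.  ``a = 0`` or ``b = 0`` denote the
    degenerate (segment) limits at ``tau = -1`` / ``tau = +1``.
    """

    a: float
    b: float
    g: float
    tau: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ParameterError("semi-axes must be non-negative")


def ellipse_axes(
    g: float | None = None, tau: float = 0.0, geff: float | None = None
) -> EllipseSpec:
    """Limiting spectral ellipse for gain ``g`` (or ``geff``) and correlation ``tau``."""
    g, _ = resolve_gain(g, geff, tau)
    return EllipseSpec(a=g * (1.0 + tau), b=g * (1.0 - tau), g=g, tau=tau)


@dataclass(frozen=True)
class Spectrum:
    """All ``N`` eigenvalues of one connectivity realization."""

    eigenvalues: np.ndarray
    params: EnsembleParams

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=complex)
        object.__setattr__(self, "eigenvalues", ev)


def eigenvalues(W: WeightMatrix) -> Spectrum:
    """Full spectrum of a (generally nonsymmetric) weight matrix.

    Exactly symmetric and exactly antisymmetric inputs are routed through
    Hermitian solvers, so the spectrum is exactly real (resp. exactly
    imaginary) in those cases; otherwise a general dense eigensolver is
    used and the spectrum is closed under conjugation because the matrix is
    real.
    """
    v = W.values
    if not np.all(np.isfinite(v)):
        raise ParameterError("weight matrix contains non-finite entries")
    if np.array_equal(v, v.T):
        ev = np.linalg.eigvalsh(v).astype(complex)
    elif np.array_equal(v, -v.T):
        # i*A is Hermitian for real antisymmetric A; eigenvalues of A are -i*mu.
        mu = np.linalg.eigvalsh(1j * v)
        ev = -1j * mu
    else:
        ev = np.linalg.eigvals(v)
    return Spectrum(eigenvalues=ev, params=W.params)


def spectrum_support_check(
    spec: Spectrum, ellipse: EllipseSpec, inflation: float = 0.05
) -> float:
    """Fraction of eigenvalues inside the ellipse inflated by ``1 + inflation``.

    Degenerate axes (``a = 0`` or ``b = 0``) are widened to a tolerance band
    of half-width ``inflation * g`` in the collapsed direction, so segment
    spectra can be checked with the same call.
    """
    ev = spec.eigenvalues
    a_inf = ellipse.a * (1.0 + inflation) if ellipse.a > 0 else inflation * ellipse.g
    b_inf = ellipse.b * (1.0 + inflation) if ellipse.b > 0 else inflation * ellipse.g
    inside = (ev.real / a_inf) ** 2 + (ev.imag / b_inf) ** 2 <= 1.0
    return float(np.mean(inside))


def _segment_potential(half_width: float, w: complex, epsabs: float) -> float:
    """Log-potential of the b -> 0 limit of the uniform ellipse on [-a, a].

    The limiting marginal of the uniform ellipse measure on its long axis is
    the semicircle density ``(2 / (pi a^2)) sqrt(a^2 - x^2)``.
    """
    a = half_width
    u, v = w.real, w.imag

    def f(x: float) -> float:
        return 0.5 * math.log((x - u) ** 2 + v * v) * math.sqrt(a * a - x * x)

    pts = [u] if (abs(v) < 1e-14 and -a < u < a) else None
    val, _ = quad(f, -a, a, points=pts, limit=300, epsabs=epsabs, epsrel=1e-13)
    return 2.0 / (math.pi * a * a) * val


def log_potential(ellipse: EllipseSpec, w: complex, epsabs: float = 1e-9) -> float:
    """Logarithmic potential ``int log|z - w| rho(z) dz`` of the uniform ellipse.

    Evaluated by nested adaptive quadrature in elliptical polar coordinates
    ``z = a r cos(theta) + i b r sin(theta)`` (Jacobian ``a b r``), which
    maps the support onto a rectangle; the integrable logarithmic
    singularity (when ``w`` lies inside the support) is isolated by passing
    its radius and angle as quadrature break points.  Degenerate supports
    (``a = 0`` or ``b = 0``) fall back to a 1-D semicircle-weighted segment
    quadrature.  Absolute accuracy is ~``epsabs`` (default well below 1e-8).
    """
    a, b = ellipse.a, ellipse.b
    w = complex(w)
    if a == 0.0 and b == 0.0:
        raise ParameterError("ellipse is fully degenerate (a = b = 0)")
    if b == 0.0:
        return _segment_potential(a, w, epsabs)
    if a == 0.0:
        # Rotate the imaginary segment onto the real axis: |i y - w| = |y - (-i w)|.
        return _segment_potential(b, -1j * w, epsabs)

    u, v = w.real, w.imag
    s = math.hypot(u / a, v / b)  # radius of the singular shell, if inside
    theta_star = math.atan2(v / b, u / a) % (2.0 * math.pi)

    def theta_integral(r: float) -> float:
        c1, c2 = a * r, b * r

        def f(th: float) -> float:
            du = c1 * math.cos(th) - u
            dv = c2 * math.sin(th) - v
            return 0.5 * math.log(du * du + dv * dv)

        pts = sorted({theta_star, (2.0 * math.pi - theta_star) % (2.0 * math.pi)})
        val, _ = quad(
            f, 0.0, 2.0 * math.pi, points=pts, limit=300,
            epsabs=epsabs / 4.0, epsrel=1e-13,
        )
        return val

    pts_r = [s] if 0.0 < s < 1.0 else None
    val, _ = quad(
        lambda r: r * theta_integral(r), 0.0, 1.0, points=pts_r, limit=200,
        epsabs=epsabs * math.pi / 2.0, epsrel=1e-13,
    )
    return val / math.pi
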