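# Methods

## Model

We study the rate network

    dx_i/dt = -x_i + sum_j w_ij S(x_j),    S(x) = tanh(x),

with the membrane time constant set to 1, so all rates and times below are
in those units. The weight matrix is Gaussian with zero mean and

    <w_ij w_kl> = (g^2/N) (delta_ik delta_jl + tau delta_il delta_jk),

i.e. marginal variance g^2/N for every entry and correlation tau between
each reciprocal pair (w_ij, w_ji); distinct unordered pairs are
independent. The sampler draws an i.i.d. standard normal matrix Z and
forms

    W = (g/sqrt(N)) (alpha Z + beta Z^T),
    alpha = (sqrt(1+tau) + sqrt(1-tau))/2,
    beta  = (sqrt(1+tau) - sqrt(1-tau))/2,

which realizes the covariance exactly (alpha^2 + beta^2 = 1,
2 alpha beta = tau) and degenerates to exact symmetry at tau = 1 and exact
antisymmetry (with a zero diagonal) at tau = -1. The same blend gives the
diagonal Var(w_ii) = g^2 (1+tau)/N, the value obtained by evaluating the
covariance at i = j; because simulation conventions for the diagonal vary,
a `zero` diagonal policy is provided as an alternative
(`EnsembleParams.diagonal_policy`). Randomness is counter-based: one root
seed plus a realization index spawn independent `SeedSequence` streams, so
sweeps are reproducible and order-independent.

## Spectral theory and the quadrature oracle

As N grows the spectrum fills the ellipse with semi-axes a = g(1+tau),
b = g(1-tau) uniformly; the rightmost extent a = geff is the effective
gain and geff = 1 the instability onset of the origin. `spectra.log_potential`
evaluates the logarithmic potential of the uniform ellipse measure,

    U(w) = \int log|z - w| rho(z) dz,

by nested adaptive quadrature in elliptical polar coordinates
(z = a r cos θ + i b r sin θ, Jacobian a b r), passing the radius and
angle of the integrable log singularity as quadrature break points. For
degenerate supports (tau = ±1) the uniform ellipse collapses onto a
segment whose limiting marginal is the semicircle density, and a 1-D
semicircle-weighted quadrature branch is used; the two branches agree with
the 2-D quadrature at tau = ±0.9999 to ~1e-3 (the residual is the genuine
b-dependence, not quadrature error). Absolute quadrature accuracy is
better than 1e-8, verified against the closed-form disk potential
|w|^2/(2g^2) - 1/2 + log g.

This quadrature is the independent oracle for the central identity: the
annealed fixed-point growth rate equals U(1), and on a 15-point grid
(geff in {1.05, 1.2, 1.5} x tau in {-0.9,...,0.9}) it matches the closed
form below to ~1e-15. The grid keeps geff > 1 throughout because the
closed form is the *interior* potential; below onset the point w = 1 lies
outside the spectral support and the identity does not apply (there the
complexity is defined to be 0 on uniqueness grounds, not by the formula).

## Complexity

The closed form

    c(g, tau) = 1/(2 g^2 (1+tau)) - 1/2 + log g
              = (1+tau)/(2 geff^2) - 1/2 + log geff - log(1+tau)

is implemented in the effective-gain form (with log1p) so the (g, tau) and
(geff, tau) parameterizations resolve to one expression and agree
bit-for-bit. The public value `c` is piecewise: 0 for geff < 1, c_raw at
or above onset; `c_contribution = max(0, c)` is the part that actually
contributes to the exponential scaling of the expected count. For tau > 0
near onset c_raw is negative — the exponential estimate then says nothing
about the (subexponential) true count, and the package reports the raw
value alongside the clipped contribution without modelling the
subexponential correction. tau = -1 raises an explicit divergence error.

The second-order onset expansion
-(geff-1) tau + (geff-1)^2 (3 tau/2 + 1) + tau/2 - log(1+tau) agrees with
the closed form to its cubic remainder; note the remainder coefficient
|f'''(1)| = |2 - 12(1+tau)| is tau-dependent (about 10 at tau = 0), so the
practical bound used in tests is 10 (geff-1)^3 rather than a fixed 1e-4.

`sign_change_tau` locates the zero crossing tau* of c_raw(geff, ·) by a
coarse geometric scan plus Brent bisection (tolerance 1e-10); near onset
tau* -> 2 (geff-1)^2.

`kac_rice_mc` estimates (1/N) log E|det(-I+W)| by log-sum-exp of
sign-magnitude log-determinants over independent draws, with a
delta-method standard error. The annealed mean of |det| is heavy-tailed
(dominated by rare draws), so the estimator is capped at N <= 100 and
documented as a trend check, not a convergent limit. An important
finite-size caveat validated here: realization-wise fixed-point counts
(the quenched picture) do *not* follow the annealed rate at small N — a
Newton census at geff = 1.5, N = 10 finds slightly *fewer* roots per
realization at negative tau even though the annealed determinant rate is
much larger there. Comparisons of the tau-dependence of c must therefore
use the annealed determinant estimator, which is what c describes.

`count_fixed_points_exhaustive` (N <= 3) uses dense sign-change bracketing
with Brent refinement at N = 1 and grid-seeded damped Newton over the
invariant box |x_i| <= sum_j |w_ij| at N = 2, 3. Below-onset uniqueness is
an asymptotic statement: at N = 1, g = 0.5 the exact mean count is
1 + 2 P(w > 1) ≈ 1.0455, and the tests assert that finite-size value.

## Dynamics

Integration is fixed-step classical RK4 with dt = 0.05 by default (the
vector field is smooth and tanh-bounded; a fixed step keeps trajectories
bit-reproducible). Convergence to a fixed point is declared when
||dx/dt||/sqrt(N) < 1e-9 at five consecutive checks spaced one time unit;
t_fp is the first crossing. The per-neuron normalization makes the
criterion N-independent. Initial conditions are Gaussian with
per-coordinate standard deviation x0_scale = 1.

The maximal Lyapunov exponent uses the Benettin method: one tangent vector
co-integrated under the exact linearized flow dv/dt = J(x(t)) v with
J = -I + W diag(1 - tanh^2 x), renormalized every 1 time unit, transient
discarded. Tangent-space propagation avoids the nonlinearity
contamination of finite trajectory separations; the two approaches agree
on test cases.

The participation ratio PR = (sum mu_i)^2 / sum mu_i^2 is computed from
singular values of the mean-centered state matrix over the measurement
window (at most 5000 stored samples per run; storage is strided, while the
path-length integral accumulates at every step). Activity statistics are
instantaneous population quantities, time-averaged over the measurement
window: sigma(t) = sqrt(mean_j x_j^2), sigma_n(t) = g sqrt(mean_j S^2),
mean sensitivity mean_j (1 - tanh^2 x_j). The transient path length is
L = N^{-1/2} \int_0^{t_fp} ||dx/dt|| dt by per-step trapezoidal
accumulation; non-convergent runs are censored (L absent, flagged), never
silently included.

`find_fixed_points` runs damped Newton (analytic Jacobian, backtracking
line search, residual tolerance 1e-12 in the max norm) from Gaussian
starts, deduplicates roots at Euclidean distance 1e-6, exploits the odd
activation's x -> -x symmetry, and reports each root's number of unstable
Jacobian directions. It is a census (lower bound), not an exhaustive
count.

`simulate_ensemble` batches many realizations through the same RK4/tangent
arithmetic using stacked matrix products, with per-run convergence
detection, censoring, and accumulators; converged runs are removed from
the batch. It agrees with the per-run functions up to floating-point
reduction order and is the engine behind the sweeps.

## Problem sizes and defaults

The sweeps ship with desk-scale defaults chosen so the full test suite and
the acceptance script each run on a single CPU in minutes: spectral edge
checks at N = 4000 (single eigendecompositions), Lyapunov checks at
N = 1000 with measurement windows of 200-300 time units, activity sweeps
at N = 500 with 20 realizations, path-length sweeps at geff = 1.2,
N = 300, 50 realizations, t_max = 750, and elliptic-law convergence checks
at N in {300, 600, 1200}. The paper-scale settings (N = 2000-4000 with
200 realizations) are reachable through the same `SweepSpec`/`SimConfig`
objects and are documented as long-running. Desk scale preserves every
trend tested here except where noted below; exact large-N curve values are
not desk-reproducible and are not asserted.

## Known limitations and one documented discrepancy

* The synthetic ensembles are dense Gaussian with pairwise reciprocal
  correlation only: no sparsity, no sign constraints (Dale's law), no
  higher-order or cyclic correlations, no low-rank structure. Conclusions
  validated on them say nothing about those structured features of real
  connectomes.
* The Kac-Rice MC estimator reports small-N trends; how fast
  (1/N) log E|det| approaches c is not quantified.
* The Newton census undercounts when basins of attraction of Newton's
  method miss roots; it is used only where a lower bound is informative.
* Activity statistics at strong anti-symmetry: for fixed geff = 1.4 and
  tau below about -0.6, the large-network regime has been described as
  saturated — activity variance growing sharply with g = geff/(1+tau) and
  mean sensitivity collapsing. Our resolved simulations do not reach that
  state: across dt in {0.05, 0.02, 0.01}, N up to 2000, horizons up to
  1500 and initial amplitudes up to x0 ~ g, the stationary state stays at
  sigma ≈ 0.6-0.8 with sensitivity ≈ 0.7-0.8, and an independently coded
  integrator reproduces this. The mechanism is a low-pass effect: at fixed
  geff, decreasing tau pushes spectral weight to frequencies of order
  g(1-tau), and the unit leak filters this fast drive, so sigma stays
  small while sigma_n tracks the growth of g (which we do reproduce and
  test). The corresponding acceptance checks assert the described
  saturated behavior and are expected to fail on this implementation; they
  are retained unmodified as an honest record of the disagreement.
* Quenched complexity, stability-index distributions, external input,
  plasticity and the full dynamical mean-field self-consistency for
  tau != 0 are out of scope.
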