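"""Closed-form and semi-analytic results for the adaptation dynamics.

Most of these results live in the *small-target limit* ``n0 -> 0``: there a
trial is rewarded only if the cursor lands (essentially) on the target, which
pins down the noise realization on the rewarded trial, so the noiseless error
evolves deterministically across *rewarded* trials even though the waiting
time between rewards is random.

Contents:

* :func:`reward_probability` — probability that a trial is rewarded given the
  current noiseless error (a Rice/noncentral-chi-square hitting probability).
* :func:`first_reward_stats` — waiting time to the first reward (geometric).
* :func:`smalltarget_trajectory` — noiseless error vs rewarded-trial count.
* :func:`worstcase_error_bound` — long-run supremum of the noiseless
  displacement under adversarial rewarded noise; yields the critical
  normalized rates 1 (perfect noiseless performance) and 2 (divergence).
* :func:`overlap`, :func:`generalization_curve` — input-profile overlap and
  the generalization of single-target adaptation across directions.
* :func:`pair_update`, :func:`interference_function`, :func:`critical_angle`
  — how a rewarded update for one target moves the error of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats

from .model import TuningField, input_activity

__all__ = [
    "reward_probability",
    "first_reward_stats",
    "FirstRewardStats",
    "smalltarget_trajectory",
    "worstcase_error_bound",
    "overlap",
    "overlap_discrete",
    "generalization_curve",
    "InterferencePair",
    "pair_update",
    "interference_function",
    "critical_angle",
]


def reward_probability(E_noiseless: float, sigma: float, n0: float) -> float:
    """Probability that the next trial is rewarded, given the noiseless error.

    The cursor-target distance ``r`` is Rice distributed with noncentrality
    ``sqrt(E_noiseless)`` and scale ``sigma`` (isotropic 2-D Gaussian noise
    around a mean offset of length ``sqrt(E_noiseless)``), so

        P = int_0^n0 (r/sigma^2) exp(-(r^2 + E)/(2 sigma^2))
                      I0(r sqrt(E)/sigma^2) dr
          = Rice CDF at n0 = 1 - MarcumQ_1(sqrt(E)/sigma, n0/sigma).

    Decreasing in ``E_noiseless``; for ``E_noiseless = 0`` it reduces to the
    Rayleigh CDF ``1 - exp(-n0^2 / (2 sigma^2))``. For fixed
    ``E_noiseless > n0**2`` it is *non-monotonic* in ``sigma``: some noise is
    needed to reach the target at all, too much scatters the endpoint.

    ``sigma = 0`` is the degenerate deterministic case: returns the indicator
    ``1{E_noiseless <= n0**2}``.
    """
    if E_noiseless < 0:
        raise ValueError("E_noiseless must be >= 0")
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return float(E_noiseless <= n0 * n0)
    b = math.sqrt(E_noiseless) / sigma
    return float(stats.rice.cdf(n0, b, scale=sigma))


def reward_probability_quadrature(
    E_noiseless: float, sigma: float, n0: float, rtol: float = 1e-10
) -> float:
    """Adaptive-quadrature evaluation of the same integral (cross-check path).

    Integrates the Rice density directly with ``scipy.integrate.quad``. Kept
    separate from :func:`reward_probability` so the two routes can be compared
    in tests; they agree to ~1e-8 over the physical parameter range.
    """
    if sigma == 0.0:
        return float(E_noiseless <= n0 * n0)
    s2 = sigma * sigma
    root_e = math.sqrt(E_noiseless)

    def density(r: float) -> float:
        # i0e avoids overflow: i0(x) = i0e(x) * exp(x)
        x = r * root_e / s2
        return (r / s2) * math.exp(-((r - root_e) ** 2) / (2.0 * s2)) * special.i0e(x)

    val, _ = integrate.quad(density, 0.0, n0, epsrel=rtol, epsabs=1e-14, limit=200)
    return float(val)


@dataclass(frozen=True)
class FirstRewardStats:
    """Waiting time to the first rewarded trial (geometric law)."""

    P1: float
    mean_trials: float

    def quantile(self, q: float) -> float:
        """Smallest trial count ``k`` with ``P(T <= k) >= q``."""
        if not (0.0 < q < 1.0):
            raise ValueError("quantile level must be in (0, 1)")
        if self.P1 == 1.0:
            return 1.0
        return float(math.ceil(math.log1p(-q) / math.log1p(-self.P1)))


def first_reward_stats(P1: float) -> FirstRewardStats:
    """Distribution of the trial index of the first reward.

    With per-trial success probability ``P1`` (the reward probability at the
    initial noiseless error, constant until the first reward because the map
    only changes on rewarded trials), the first-reward time is geometric with
    mean ``1 / P1``. ``P1 = 0`` gives an infinite mean, flagged as ``inf``.
    """
    if not (0.0 <= P1 <= 1.0):
        raise ValueError("P1 must be a probability")
    mean = math.inf if P1 == 0.0 else 1.0 / P1
    return FirstRewardStats(P1=P1, mean_trials=mean)


def smalltarget_trajectory(
    E0: float, eta_tilde: float, k: int | np.ndarray
) -> float | np.ndarray:
    """Noiseless error after ``k`` rewarded trials in the small-target limit.

    Each rewarded trial contracts the noiseless displacement by
    ``(1 - eta_tilde)``, so ``E_k = (1 - eta_tilde)**(2k) * E0``. Converges
    to zero iff ``0 < eta_tilde < 2`` and diverges for ``eta_tilde > 2``;
    at exactly 2 the error neither decays nor grows.
    """
    if E0 < 0:
        raise ValueError("E0 must be >= 0")
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("rewarded-trial index must be >= 0")
    out = E0 * (1.0 - eta_tilde) ** (2.0 * k)
    return float(out) if out.ndim == 0 else out


def critical_rate_scan(
    E0: float,
    rate_grid: np.ndarray,
    n_rewarded: int = 500,
    shrink: float = 0.5,
    grow: float = 2.0,
) -> tuple[float, np.ndarray]:
    """Locate the convergence/divergence boundary of the rewarded-trial recursion.

    Iterates ``E <- (1 - eta_tilde)**2 * E`` for ``n_rewarded`` steps at every
    rate in ``rate_grid`` and classifies each endpoint: tending to zero
    (``< shrink * E0``), growing without bound (``> grow * E0``), or marginal
    (possible only where the contraction factor is exactly 1). Returns the
    midpoint between the largest converging and the smallest diverging rate,
    plus the per-rate classification (+1 diverged, -1 converged, 0 marginal).
    """
    rate_grid = np.asarray(rate_grid, dtype=float)
    labels = np.zeros(rate_grid.shape, dtype=int)
    for j, et in enumerate(rate_grid):
        E = E0
        contraction = (1.0 - et) ** 2
        for _ in range(n_rewarded):
            E *= contraction
            if E > 1e30 * E0:  # unbounded growth; stop before overflow
                break
        if E < shrink * E0:
            labels[j] = -1
        elif E > grow * E0:
            labels[j] = +1
    converging = rate_grid[labels == -1]
    diverging = rate_grid[labels == +1]
    if converging.size == 0 or diverging.size == 0:
        raise ValueError("rate grid does not bracket the convergence boundary")
    boundary = 0.5 * (converging.max() + diverging.min())
    return float(boundary), labels


def worstcase_error_bound(
    eta_tilde: float, n0: float, max_iter: int = 100_000, rtol: float = 1e-12
) -> float:
    """Long-run supremum of the noiseless displacement ``sqrt(E)`` under
    adversarial rewarded noise.

    With a finite target, a rewarded trial only constrains the cursor to lie
    within distance ``n0`` of the target center. The worst admissible reward
    placement obeys ``|d_{k+1}| = |1 - eta_tilde| * |d_k| + eta_tilde * n0``;
    the bound is the fixed point of this recursion, obtained here by
    iterating it (the closed forms ``n0`` for ``eta_tilde <= 1``,
    ``eta_tilde * n0 / (2 - eta_tilde)`` for ``1 < eta_tilde < 2`` and
    ``+inf`` for ``eta_tilde >= 2`` drop out of the iteration).

    Consequences: noiseless performance is perfect (the error never leaves
    the target) exactly when ``eta_tilde <= 1``; the support becomes
    unbounded at ``eta_tilde = 2``.
    """
    if eta_tilde < 0:
        raise ValueError("eta_tilde must be >= 0")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if eta_tilde == 0.0:
        return 0.0
    a = abs(1.0 - eta_tilde)
    if a >= 1.0:  # eta_tilde >= 2: the recursion has no finite fixed point
        return math.inf
    d = 0.0
    for _ in range(max_iter):
        d_next = a * d + eta_tilde * n0
        if abs(d_next - d) <= rtol * max(d_next, n0):
            return float(d_next)
        d = d_next
    return float(d)


def overlap(delta_theta: float | np.ndarray, field: TuningField) -> float | np.ndarray:
    """Normalized overlap of input profiles for directions ``delta_theta`` apart.

    Large-``N`` closed form for the Von Mises tuning curve:

        Gamma(dtheta) = I0(2 rho cos(dtheta/2)) / I0(2 rho),

    which is the continuum limit of ``u(theta) . u(theta + dtheta) / ||u||^2``
    and is independent of ``theta``. Always in ``(0, 1]`` with
    ``Gamma(0) = 1``; flat tuning (``rho = 0``) gives 1 everywhere, narrow
    tuning concentrates the overlap near ``dtheta = 0``.

    Evaluated with exponentially scaled Bessel functions so large ``rho`` is
    safe.
    """
    dtheta = np.asarray(delta_theta, dtype=float)
    rho = field.rho
    if rho == 0.0:
        out = np.ones_like(dtheta)
        return float(out) if out.ndim == 0 else out
    x = 2.0 * rho * np.cos(dtheta / 2.0)
    # i0(x)/i0(2 rho) = i0e(x) * exp(x - 2 rho) / i0e(2 rho); x <= 2 rho
    out = special.i0e(np.abs(x)) * np.exp(np.abs(x) - 2.0 * rho) / special.i0e(2.0 * rho)
    return float(out) if out.ndim == 0 else out


def overlap_discrete(delta_theta: float, field: TuningField, theta: float = 0.0) -> float:
    """Discrete-sum overlap ``u(theta) . u(theta+dtheta) / ||u(theta)||^2``.

    Matches :func:`overlap` to high accuracy for moderate ``N``; kept as the
    exact finite-``N`` definition and as a cross-check of the Bessel form.
    """
    u1 = input_activity(theta, field)
    u2 = input_activity(theta + delta_theta, field)
    return float(u1 @ u2 / (u1 @ u1))


def generalization_curve(
    delta_theta: float | np.ndarray, field: TuningField
) -> float | np.ndarray:
    """Generalization of single-target adaptation to a test direction.

    After full adaptation to one target in the small-target limit, the
    relative reduction of the noiseless error at a test target
    ``delta_theta`` away is

        G(dtheta) = Gamma * (2 cos(dtheta) - Gamma),

    with ``Gamma`` the overlap. ``G(0) = 1`` (perfect at the trained
    direction); ``G < 0`` — performance *worse* than before adaptation —
    whenever ``cos(dtheta) < Gamma / 2``, which happens for far targets under
    broad tuning. The tuning width enters only through ``Gamma``.
    """
    g = overlap(delta_theta, field)
    return g * (2.0 * np.cos(np.asarray(delta_theta, dtype=float)) - g)


@dataclass(frozen=True)
class InterferencePair:
    """Noiseless displacements of two targets and their coupling.

    ``d`` is the planar noiseless displacement (rotated mean endpoint minus
    target) of the target about to be rewarded; ``d_other`` the same for the
    other target; ``Gamma`` the overlap of their input profiles;
    ``delta_theta`` their angular separation.
    """

    d: np.ndarray
    d_other: np.ndarray
    Gamma: float
    delta_theta: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.Gamma <= 1.0):
            raise ValueError("overlap must lie in [-1, 1]")

    @property
    def E(self) -> float:
        return float(self.d @ self.d)

    @property
    def E_other(self) -> float:
        return float(self.d_other @ self.d_other)


def pair_update(pair: InterferencePair, eta_tilde: float) -> InterferencePair:
    """One rewarded trial for the first target, in the small-target limit.

    The rewarded target's displacement contracts, ``d <- (1 - eta_tilde) d``;
    the other target's displacement picks up a leaked copy through the
    overlapping input representation, ``d_other <- d_other - eta_tilde *
    Gamma * d_old``. With disjoint representations (``Gamma = 0``) the two
    adaptation processes are independent.
    """
    d_old = np.asarray(pair.d, dtype=float)
    return InterferencePair(
        d=(1.0 - eta_tilde) * d_old,
        d_other=np.asarray(pair.d_other, dtype=float) - eta_tilde * pair.Gamma * d_old,
        Gamma=pair.Gamma,
        delta_theta=pair.delta_theta,
    )


def interference_function(
    delta_theta: float | np.ndarray, eta_tilde: float, field: TuningField
) -> float | np.ndarray:
    """Relative error reduction for target B after the *first* rewarded trial
    for target A.

    Before any learning both targets carry displacements of equal magnitude
    subtending the angle ``delta_theta`` (both are the same rotation applied
    to unit vectors ``delta_theta`` apart). One rewarded trial for A changes
    B's noiseless error by the factor ``1 - I1`` with

        I1(dtheta) = eta_tilde * Gamma * (2 cos(dtheta) - eta_tilde * Gamma).

    Positive ``I1`` is constructive interference (B improves too), negative
    is destructive; the transition sits at ``cos(dtheta) = eta_tilde *
    Gamma / 2``. At ``eta_tilde = 1`` the interference function coincides
    with the generalization curve ``G``.
    """
    g = eta_tilde * overlap(delta_theta, field)
    return g * (2.0 * np.cos(np.asarray(delta_theta, dtype=float)) - g)


def critical_angle(
    eta_tilde: float, field: TuningField, n_scan: int = 2048
) -> float | None:
    """Interior extremum of the interference function on ``(0, pi)``.

    Finds a sign change of ``dI1/d(dtheta)`` by scanning and polishes it with
    bracketed root-finding. A sign change exists only in the non-monotonic
    regime (sufficiently narrow tuning); if ``I1`` is monotone on the
    interval, returns ``None``.
    """
    eps = 1e-6

    def deriv(x: float) -> float:
        h = 1e-6
        a = interference_function(x + h, eta_tilde, field)
        b = interference_function(x - h, eta_tilde, field)
        return float(a - b) / (2.0 * h)

    xs = np.linspace(eps, np.pi - eps, n_scan)
    ds = np.array([deriv(x) for x in xs])
    sign_changes = np.nonzero(np.diff(np.sign(ds)) != 0)[0]
    if sign_changes.size == 0:
        return None
    i = sign_changes[0]
    return float(optimize.brentq(deriv, xs[i], xs[i + 1], xtol=1e-10))
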