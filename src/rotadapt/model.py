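"""Core network model for reward-gated visuomotor rotation adaptation.

The model is a two-layer linear network. An input layer of ``N`` directionally
tuned neurons encodes the target direction with Von Mises tuning curves; a
two-unit output layer encodes the planar hand endpoint through a ``2 x N``
connectivity matrix ``W``. A visuomotor rotation by angle ``gamma`` is applied
to the (noisy) output to produce the cursor endpoint, and a scalar reward
gates a Hebbian, noise-driven weight update — a REINFORCE-style rule in which
the only teaching signal is the reward.

Conventions
-----------
* Angles are radians; directions live in ``[0, 2*pi)``.
* The rotation ``R_gamma`` is counter-clockwise.
* The output noise ``xi`` is 2-D isotropic Gaussian with SD ``sigma`` per
  component.
* "Target size" ``n0`` is the target *radius*; reward is delivered when the
  squared cursor-target distance satisfies ``E <= n0**2`` (non-strict — the
  boundary has measure zero under the noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "TuningField",
    "Connectivity",
    "TaskGeometry",
    "NoiseSpec",
    "LearningSpec",
    "TrialRecord",
    "input_activity",
    "half_bandwidth",
    "init_connectivity",
    "rotation_matrix",
    "trial_outcome",
    "binary_reward",
    "update_weights",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class TuningField:
    """Input-layer population of directionally tuned neurons.

    Neuron ``i`` responds to a target in direction ``theta`` with

        u_i(theta) = Lambda * exp(rho * (cos(theta - theta_i) - 1)),

    a Von Mises profile peaking at ``Lambda`` for ``theta == theta_i`` with
    baseline ``Lambda * exp(-2 * rho)``. Preferred directions ``theta_i`` are
    evenly spaced on the circle. The peak ``Lambda`` is set so that the
    squared population norm ``||u(theta)||**2`` equals ``U_target`` for every
    direction (exact up to grid effects that vanish exponentially in ``N``);
    holding the norm fixed as ``rho`` varies makes the single-target learning
    time independent of the tuning width.

    Parameters
    ----------
    N : int
        Number of input neurons.
    rho : float
        Tuning concentration (>= 0). ``rho = 0`` is flat tuning; larger
        ``rho`` means narrower tuning.
    U_target : float
        Required squared population norm after normalization (default 1).
    """

    N: int
    rho: float
    U_target: float = 1.0
    Lambda: float = field(init=False)
    preferred_dirs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError(f"need at least 4 input neurons, got N={self.N}")
        if self.rho < 0:
            raise ValueError(f"tuning concentration must be >= 0, got rho={self.rho}")
        if self.U_target <= 0:
            raise ValueError("U_target must be positive")
        dirs = TWO_PI * np.arange(self.N) / self.N
        # discrete norm sum evaluated at theta = 0; theta-dependence is
        # O(exp(-N)) and checked by normalization_residual()
        s = np.sum(np.exp(2.0 * self.rho * (np.cos(dirs) - 1.0)))
        object.__setattr__(self, "Lambda", float(np.sqrt(self.U_target / s)))
        object.__setattr__(self, "preferred_dirs", dirs)

    @property
    def eta_scale(self) -> float:
        """Squared population norm ``||u||**2`` (== U_target by construction)."""
        return self.U_target

    def normalization_residual(self, n_grid: int = 720) -> float:
        """Max relative deviation of ``||u(theta)||**2`` from ``U_target`` on a grid."""
        grid = TWO_PI * np.arange(n_grid) / n_grid
        norms = np.array([np.dot(u, u) for u in (input_activity(t, self) for t in grid)])
        return float(np.max(np.abs(norms - self.U_target)) / self.U_target)

    def first_fourier_coefficient(self) -> float:
        """First Fourier coefficient ``f1`` of the tuning curve.

        ``f1 = (1/2pi) * int g(x) cos(x) dx`` for
        ``g(x) = Lambda * exp(rho*(cos x - 1))``, i.e.
        ``Lambda * exp(-rho) * I1(rho)``.
        """
        return float(self.Lambda * np.exp(-self.rho) * special.i1(self.rho))


def input_activity(theta: float, field: TuningField) -> np.ndarray:
    """Population activity vector ``u(theta)`` of the input layer."""
    return field.Lambda * np.exp(field.rho * (np.cos(theta - field.preferred_dirs) - 1.0))


def half_bandwidth(rho: float) -> float:
    """Tuning-curve width at half the peak-to-baseline range.

    Solves ``exp(rho*(cos(x) - 1)) = (1 + exp(-2*rho)) / 2`` for ``x`` in
    ``(0, pi)``. Strictly decreasing in ``rho``; returns ``pi`` for flat
    tuning (``rho = 0``), where the half-height level is never crossed.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if rho == 0.0:
        return np.pi
    half_level = 0.5 * (1.0 + np.exp(-2.0 * rho))
    # cos(x) = 1 + log(half_level)/rho has a solution in (0, pi) for rho > 0
    c = 1.0 + np.log(half_level) / rho
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass(frozen=True)
class Connectivity:
    """Sensorimotor map: ``2 x N`` weight matrix from input layer to output units."""

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape[0] != 2 or W.ndim != 2:
            raise ValueError(f"W must have shape (2, N), got {W.shape}")
        object.__setattr__(self, "W", W)

    @property
    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.W))

    def copy(self) -> "Connectivity":
        return Connectivity(self.W.copy())


def rotation_matrix(gamma: float) -> np.ndarray:
    """Counter-clockwise planar rotation by ``gamma`` radians."""
    c, s = np.cos(gamma), np.sin(gamma)
    return np.array([[c, -s], [s, c]])


def init_connectivity(field: TuningField, n_grid: int = 720, rcond: float = 1e-8) -> Connectivity:
    """Pre-perturbation map ``W0`` with zero noiseless error for every target.

    ``W0`` is the minimum-norm least-squares solution of
    ``W0 @ u(theta) = v(theta)`` over a fine grid of directions (before any
    rotation is imposed), which for non-degenerate tuning coincides with the
    analytic form whose rows are ``(cos theta_i, sin theta_i) / (N * f1)``
    with ``f1`` the first Fourier coefficient of the tuning curve. The
    least-squares route is preferred because it stays well-conditioned when
    higher Fourier components are only approximately zero.

    Raises
    ------
    ValueError
        For flat tuning (``rho = 0``): the first Fourier coefficient
        vanishes, the target direction is unrecoverable from ``u`` and no
        ``W0`` can satisfy the constraint.
    """
    if field.rho == 0.0:
        raise ValueError(
            "cannot initialize connectivity for flat tuning (rho=0): the first "
            "Fourier coefficient of the tuning curve vanishes, so the input "
            "population carries no information about the target direction"
        )
    thetas = TWO_PI * np.arange(n_grid) / n_grid
    U = np.stack([input_activity(t, field) for t in thetas])  # (n_grid, N)
    V = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)  # (n_grid, 2)
    # W0 @ u = v  <=>  U @ W0.T = V, min-norm via pseudo-inverse. Singular
    # directions correspond to Fourier modes of the tuning curve; modes whose
    # coefficient is below rcond carry only rounding noise and are truncated.
    W0T, *_ = np.linalg.lstsq(U, V, rcond=rcond)
    return Connectivity(W0T.T)


def analytic_connectivity(field: TuningField) -> Connectivity:
    """Closed-form ``W0`` from the Fourier expansion (cross-check for
    :func:`init_connectivity`)."""
    f1 = field.first_fourier_coefficient()
    if f1 <= 0:
        raise ValueError("first Fourier coefficient vanishes (rho=0)")
    dirs = field.preferred_dirs
    W0 = np.stack([np.cos(dirs), np.sin(dirs)]) / (field.N * f1)
    return Connectivity(W0)


@dataclass(frozen=True)
class TaskGeometry:
    """One target with the imposed rotation and the reward threshold.

    theta : target direction (radians); the target sits at unit distance.
    gamma : imposed visuomotor rotation (radians, counter-clockwise).
    n0    : target radius; reward iff squared error ``E <= n0**2``.
    """

    theta: float
    gamma: float = 0.0
    n0: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.n0 < 1.0):
            raise ValueError(f"target radius must be in [0, 1), got n0={self.n0}")

    @property
    def v_target(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])

    @property
    def R_gamma(self) -> np.ndarray:
        return rotation_matrix(self.gamma)


@dataclass(frozen=True)
class NoiseSpec:
    """Isotropic 2-D Gaussian output noise; ``sigma`` is the per-component SD."""

    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class LearningSpec:
    """Learning rate and its normalized counterpart.

    The normalized rate ``eta_tilde = eta * ||u||**2`` is the per-rewarded-
    trial contraction parameter: a rewarded trial whose noise exactly cancels
    the residual displacement scales the noiseless displacement by
    ``(1 - eta_tilde)``.
    """

    eta: float
    U: float = 1.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.U <= 0:
            raise ValueError("U must be positive")

    @property
    def eta_tilde(self) -> float:
        return self.eta * self.U

    @classmethod
    def from_eta_tilde(cls, eta_tilde: float, field: TuningField) -> "LearningSpec":
        """Build from the normalized rate for a given tuning field."""
        U = field.eta_scale
        return cls(eta=eta_tilde / U, U=U)


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial outcome: errors, reward, and the shaping state in force."""

    t: int
    target_index: int
    E: float
    E_noiseless: float
    R: float
    n0_t: float
    gamma_t: float


def trial_outcome(
    W: Connectivity | np.ndarray,
    geom: TaskGeometry,
    xi: np.ndarray,
    field: TuningField,
) -> tuple[float, float, np.ndarray]:
    """Execute one reach: returns ``(E, E_noiseless, cursor_endpoint)``.

    The hand endpoint is ``y = W @ u(theta) + xi``; the cursor is the rotated
    hand endpoint ``c = R_gamma @ y``; ``E = |c - v|**2``. The noiseless
    error ``E_noiseless = |R_gamma @ W @ u - v|**2`` removes the noise term
    and changes only when ``W`` changes.
    """
    Wm = W.W if isinstance(W, Connectivity) else np.asarray(W)
    u = input_activity(geom.theta, field)
    Rg = geom.R_gamma
    y_mean = Wm @ u
    cursor = Rg @ (y_mean + xi)
    v = geom.v_target
    d = cursor - v
    d0 = Rg @ y_mean - v
    return float(d @ d), float(d0 @ d0), cursor


def binary_reward(E: float, n0: float) -> int:
    """All-or-none reward: 1 iff the cursor lands within the target disc."""
    return int(E <= n0 * n0)


def update_weights(
    W: Connectivity | np.ndarray,
    R: float,
    xi: np.ndarray,
    u: np.ndarray,
    eta: float,
) -> Connectivity:
    """Reward-gated Hebbian update ``W' = W + eta * R * outer(xi, u)``.

    The update correlates the output perturbation ``xi`` with the input
    activity ``u`` and is gated by the reward: with ``R = 0`` the map is
    unchanged; a graded reward scales the step linearly.
    """
    Wm = W.W if isinstance(W, Connectivity) else np.asarray(W)
    if R == 0:
        return Connectivity(Wm.copy())
    return Connectivity(Wm + eta * R * np.outer(xi, u))
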