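"""Trial-loop engine: presentation schedules, reward families, shaping.

:func:`run_adaptation` executes the per-trial loop for a single realization
(select target -> input activity -> draw noise -> reach -> reward -> gated
weight update -> shaping controller step) and records every trial.
:func:`run_ensemble` runs many independent realizations of the same
configuration with the arithmetic vectorized across realizations, which is
what the ensemble statistics are computed from.

Shaping controllers implement the two curricula studied with this model:
gradually shrinking the target once the reward rate has reached a steady
state, and gradually growing the imposed rotation either on a fixed block
schedule or adaptively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .model import (
    Connectivity,
    LearningSpec,
    NoiseSpec,
    TaskGeometry,
    TrialRecord,
    TuningField,
    init_connectivity,
    input_activity,
    rotation_matrix,
)

__all__ = [
    "RewardSpec",
    "ScheduleSpec",
    "ShapingSpec",
    "TaskSpec",
    "RunResult",
    "EnsembleResult",
    "reward_value",
    "run_adaptation",
    "run_ensemble",
    "evaluate_generalization",
    "realization_rng",
]

DIVERGENCE_GUARD = 1e6  # terminate when the noiseless error exceeds this


@dataclass(frozen=True)
class RewardSpec:
    """Reward-function family.

    ``binary``: all-or-none, 1 iff ``E <= n0**2``.
    ``smooth_deterministic``: logistic in the squared error,
        ``sigma_T(E) = 1 / (1 + exp((E - n0**2) / T))`` — equals 1/2 at the
        target boundary and recovers the binary reward pointwise as
        ``T -> 0``.
    ``stochastic_bernoulli``: a Bernoulli draw with success probability
        ``sigma_T(E)``, i.e. the same graded information delivered through a
        binary channel.

    ``T`` is the smoothing parameter (units of squared error); required
    positive for the non-binary families.
    """

    family: Literal["binary", "smooth_deterministic", "stochastic_bernoulli"] = "binary"
    T: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("binary", "smooth_deterministic", "stochastic_bernoulli"):
            raise ValueError(f"unknown reward family {self.family!r}")
        if self.family != "binary" and self.T <= 0:
            raise ValueError(f"family {self.family!r} requires smoothing T > 0")


def smooth_reward(E: float | np.ndarray, n0: float, T: float) -> float | np.ndarray:
    """Logistic reward ``1 / (1 + exp((E - n0**2) / T))``."""
    from scipy.special import expit

    out = expit(-(np.asarray(E, dtype=float) - n0 * n0) / T)
    return float(out) if out.ndim == 0 else out


def reward_value(
    E: float, spec: RewardSpec, n0: float, rng: np.random.Generator | None = None
) -> float:
    """Reward delivered for a trial with squared error ``E``."""
    if spec.family == "binary":
        return float(E <= n0 * n0)
    p = smooth_reward(E, n0, spec.T)
    if spec.family == "smooth_deterministic":
        return float(p)
    if rng is None:
        raise ValueError("stochastic_bernoulli reward requires an rng")
    return float(rng.random() < p)


@dataclass(frozen=True)
class ScheduleSpec:
    """Target-presentation schedule.

    ``cyclic`` presents the ``m`` targets in fixed alternation starting from
    index ``start_index``; ``random_uniform`` draws the target independently
    and uniformly on every trial. Default directions are evenly spaced over
    the circle.
    """

    m: int = 1
    mode: Literal["cyclic", "random_uniform"] = "cyclic"
    target_dirs: tuple[float, ...] | None = None
    start_index: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one target")
        if self.target_dirs is not None and len(self.target_dirs) != self.m:
            raise ValueError("target_dirs length must equal m")

    def directions(self) -> np.ndarray:
        if self.target_dirs is not None:
            return np.asarray(self.target_dirs, dtype=float)
        return 2.0 * np.pi * np.arange(self.m) / self.m

    def sequence(self, n_trials: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "cyclic":
            return (self.start_index + np.arange(n_trials)) % self.m
        return rng.integers(0, self.m, size=n_trials)


@dataclass(frozen=True)
class ShapingSpec:
    """Curriculum controller configuration.

    ``target_size``: start with a large target of radius ``n0_init`` and
    shrink it by ``n0_step`` (never below ``n0_final``) whenever the
    monitored reward rates have reached a steady state. Steadiness is
    declared when every monitored per-target exponential moving average
    (timescale ``ema_timescale`` trials) has changed by less than
    ``steady_tol`` over one timescale; the EMAs are then reset to zero.
    With ``per_target_monitoring`` every target's EMA must be steady,
    otherwise a single pooled EMA is used.

    ``rotation_angle``: start unrotated and grow the rotation by
    ``gamma_step`` toward the task's final angle — every ``block_len``
    trials (``adaptive=False``) or on EMA steady state (``adaptive=True``).
    """

    kind: Literal["none", "target_size", "rotation_angle"] = "none"
    n0_init: float = 0.4
    n0_step: float = 0.05
    n0_final: float = 0.1
    gamma_step: float = np.deg2rad(5.0)
    block_len: int = 25
    ema_timescale: float = 100.0
    steady_tol: float = 0.02
    per_target_monitoring: bool = True
    adaptive: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("none", "target_size", "rotation_angle"):
            raise ValueError(f"unknown shaping kind {self.kind!r}")
        if self.kind == "target_size" and self.n0_init < self.n0_final:
            raise ValueError("n0_init must be >= n0_final")
        if self.n0_step <= 0 or self.block_len <= 0 or self.ema_timescale <= 0:
            raise ValueError("shaping steps/timescales must be positive")


class _ShapingState:
    """Mutable per-run state of the shaping controller."""

    def __init__(self, spec: ShapingSpec, m: int, n0_task: float, gamma_task: float):
        self.spec = spec
        if spec.kind == "target_size":
            self.n0 = spec.n0_init
            self.gamma = gamma_task
        elif spec.kind == "rotation_angle":
            self.n0 = n0_task
            self.gamma = 0.0
        else:
            self.n0 = n0_task
            self.gamma = gamma_task
        self.gamma_final = gamma_task
        n_mon = m if spec.per_target_monitoring else 1
        self.ema = np.zeros(n_mon)
        self.ema_prev = np.zeros(n_mon)
        self.alpha = 1.0 / spec.ema_timescale
        self.trials_since_check = 0
        self.transitions: list[tuple[int, float, float]] = []  # (t, n0, gamma)

    def step(self, t: int, target_index: int, R: float) -> None:
        spec = self.spec
        if spec.kind == "none":
            return
        if spec.kind == "rotation_angle" and not spec.adaptive:
            if (t + 1) % spec.block_len == 0 and self.gamma < self.gamma_final:
                self.gamma = min(self.gamma + spec.gamma_step, self.gamma_final)
                self.transitions.append((t + 1, self.n0, self.gamma))
            return
        # adaptive variants: track reward EMA(s)
        j = target_index if spec.per_target_monitoring else 0
        self.ema[j] += self.alpha * (R - self.ema[j])
        self.trials_since_check += 1
        if self.trials_since_check < spec.ema_timescale:
            return
        self.trials_since_check = 0
        steady = bool(np.all(np.abs(self.ema - self.ema_prev) < spec.steady_tol))
        self.ema_prev = self.ema.copy()
        if not steady:
            return
        if spec.kind == "target_size":
            if self.n0 > spec.n0_final:
                self.n0 = max(self.n0 - spec.n0_step, spec.n0_final)
                self.ema[:] = 0.0
                self.ema_prev[:] = 0.0
                self.transitions.append((t + 1, self.n0, self.gamma))
        else:  # adaptive rotation
            if self.gamma < self.gamma_final:
                self.gamma = min(self.gamma + spec.gamma_step, self.gamma_final)
                self.ema[:] = 0.0
                self.ema_prev[:] = 0.0
                self.transitions.append((t + 1, self.n0, self.gamma))


@dataclass(frozen=True)
class TaskSpec:
    """Static task definition: tuning field, final rotation, target radius, reward."""

    field: TuningField
    gamma: float
    n0: float
    reward: RewardSpec = RewardSpec()


@dataclass
class RunResult:
    """Full seeded time series of one adaptation run.

    Trial data are stored as flat arrays (one entry per trial); the
    ``records`` iterator and ``to_frame`` provide per-trial record views.
    """

    t: np.ndarray
    target_index: np.ndarray
    E: np.ndarray
    E_noiseless: np.ndarray
    R: np.ndarray
    n0_t: np.ndarray
    gamma_t: np.ndarray
    W_final: Connectivity
    seed: int
    config_snapshot: dict
    divergent: bool = False
    shaping_transitions: tuple = ()

    @property
    def n_trials(self) -> int:
        return len(self.t)

    @property
    def records(self) -> Iterator[TrialRecord]:
        for i in range(self.n_trials):
            yield TrialRecord(
                t=int(self.t[i]),
                target_index=int(self.target_index[i]),
                E=float(self.E[i]),
                E_noiseless=float(self.E_noiseless[i]),
                R=float(self.R[i]),
                n0_t=float(self.n0_t[i]),
                gamma_t=float(self.gamma_t[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "target_index": self.target_index,
                "E": self.E,
                "E_noiseless": self.E_noiseless,
                "R": self.R,
                "n0_t": self.n0_t,
                "gamma_t": self.gamma_t,
            }
        )

    def target_series(self, j: int, noiseless: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(trial indices, error series) restricted to presentations of target ``j``."""
        mask = self.target_index == j
        e = self.E_noiseless if noiseless else self.E
        return self.t[mask], e[mask]


def realization_rng(base_seed: int, index: int = 0) -> np.random.Generator:
    """Counter-based per-realization stream: independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(index,)))


def run_adaptation(
    task: TaskSpec,
    schedule: ScheduleSpec,
    shaping: ShapingSpec,
    noise: NoiseSpec,
    learning: LearningSpec,
    n_trials: int,
    seed: int,
    realization: int = 0,
    W0: Connectivity | None = None,
) -> RunResult:
    """Run one seeded realization of the adaptation experiment.

    The rotation is in force from trial 0 onward, so the trial-0 error is
    the already-rotated error. Runs whose noiseless error exceeds
    ``DIVERGENCE_GUARD`` terminate early with ``divergent=True``, keeping
    the records accumulated so far.
    """
    fld = task.field
    rng = realization_rng(seed, realization)
    dirs = schedule.directions()
    m = schedule.m
    U = np.stack([input_activity(th, fld) for th in dirs])  # (m, N)
    V = np.stack([np.cos(dirs), np.sin(dirs)], axis=1)  # (m, 2)
    W = (W0.W if W0 is not None else init_connectivity(fld).W).copy()
    state = _ShapingState(shaping, m, task.n0, task.gamma)
    seq = schedule.sequence(n_trials, rng)
    binary = task.reward.family == "binary"
    bernoulli = task.reward.family == "stochastic_bernoulli"

    E_arr = np.empty(n_trials)
    En_arr = np.empty(n_trials)
    R_arr = np.empty(n_trials)
    n0_arr = np.empty(n_trials)
    g_arr = np.empty(n_trials)
    sigma, eta = noise.sigma, learning.eta
    divergent = False
    n_done = n_trials
    gamma_cur = None
    Rg = None
    for tt in range(n_trials):
        j = seq[tt]
        if state.gamma != gamma_cur:
            gamma_cur = state.gamma
            Rg = rotation_matrix(gamma_cur)
        n0_cur = state.n0
        u = U[j]
        xi = sigma * rng.standard_normal(2)
        y = W @ u
        v = V[j]
        c = Rg @ (y + xi)
        d = c - v
        E = d @ d
        d0 = Rg @ y - v
        En = d0 @ d0
        if binary:
            R = 1.0 if E <= n0_cur * n0_cur else 0.0
        else:
            p = smooth_reward(E, n0_cur, task.reward.T)
            R = float(rng.random() < p) if bernoulli else float(p)
        if R != 0.0:
            W += (eta * R) * np.outer(xi, u)
        E_arr[tt] = E
        En_arr[tt] = En
        R_arr[tt] = R
        n0_arr[tt] = n0_cur
        g_arr[tt] = gamma_cur
        if En > DIVERGENCE_GUARD or not np.isfinite(En):
            divergent = True
            n_done = tt + 1
            break
        state.step(tt, int(j), R)

    sl = slice(0, n_done)
    config = {
        "N": fld.N,
        "rho": fld.rho,
        "U_target": fld.U_target,
        "gamma": task.gamma,
        "n0": task.n0,
        "reward": {"family": task.reward.family, "T": task.reward.T},
        "schedule": {"m": m, "mode": schedule.mode, "target_dirs": dirs.tolist()},
        "shaping": {"kind": shaping.kind},
        "sigma": sigma,
        "eta": eta,
        "eta_tilde": learning.eta_tilde,
        "n_trials": n_trials,
        "seed": seed,
        "realization": realization,
    }
    return RunResult(
        t=np.arange(n_done),
        target_index=seq[sl].astype(int),
        E=E_arr[sl],
        E_noiseless=En_arr[sl],
        R=R_arr[sl],
        n0_t=n0_arr[sl],
        gamma_t=g_arr[sl],
        W_final=Connectivity(W),
        seed=seed,
        config_snapshot=config,
        divergent=divergent,
        shaping_transitions=tuple(state.transitions),
    )


@dataclass
class EnsembleResult:
    """Stacked trial data for many realizations of one configuration.

    ``E``/``E_noiseless``/``R`` have shape ``(n_realizations, n_trials)``;
    ``target_index`` has shape ``(n_trials,)`` for shared (cyclic) schedules
    and ``(n_realizations, n_trials)`` for per-realization random schedules.
    """

    E: np.ndarray
    E_noiseless: np.ndarray
    R: np.ndarray
    target_index: np.ndarray
    dirs: np.ndarray
    n0: float
    gamma: float
    seed: int
    divergent: np.ndarray  # (n_realizations,) bool

    @property
    def n_realizations(self) -> int:
        return self.E.shape[0]

    @property
    def n_trials(self) -> int:
        return self.E.shape[1]

    def target_mask(self, j: int) -> np.ndarray:
        """Boolean mask over trials (shared schedule) or (real, trial) grid."""
        return self.target_index == j


def run_ensemble(
    task: TaskSpec,
    schedule: ScheduleSpec,
    noise: NoiseSpec,
    learning: LearningSpec,
    n_trials: int,
    n_realizations: int,
    seed: int,
) -> EnsembleResult:
    """Run ``n_realizations`` independent realizations, vectorized across them.

    Shaping is not supported here (the controllers are per-run stateful);
    use :func:`run_adaptation` per realization for shaped ensembles. The
    noise streams of the realizations are drawn from one counter-based
    generator, so the ensemble is reproducible from ``seed`` alone.
    """
    fld = task.field
    rng = realization_rng(seed)
    dirs = schedule.directions()
    m = schedule.m
    U = np.stack([input_activity(th, fld) for th in dirs])  # (m, N)
    V = np.stack([np.cos(dirs), np.sin(dirs)], axis=1)  # (m, 2)
    W0 = init_connectivity(fld).W
    R_real = n_realizations
    W = np.broadcast_to(W0, (R_real, 2, fld.N)).copy()
    Rg = rotation_matrix(task.gamma)
    n0sq = task.n0 * task.n0
    sigma, eta = noise.sigma, learning.eta
    binary = task.reward.family == "binary"
    bernoulli = task.reward.family == "stochastic_bernoulli"
    shared = schedule.mode == "cyclic"
    if shared:
        seq = schedule.sequence(n_trials, rng)
    else:
        seq = rng.integers(0, m, size=(R_real, n_trials))

    E = np.empty((R_real, n_trials))
    En = np.empty((R_real, n_trials))
    Rw = np.empty((R_real, n_trials))
    alive = np.ones(R_real, dtype=bool)
    for tt in range(n_trials):
        xi = sigma * rng.standard_normal((R_real, 2))
        if shared:
            j = seq[tt]
            u = U[j]  # (N,)
            y = W @ u  # (R, 2)
            v = V[j]
            c = (y + xi) @ Rg.T
            d = c - v
            d0 = y @ Rg.T - v
        else:
            j = seq[:, tt]
            u = U[j]  # (R, N)
            y = np.einsum("rij,rj->ri", W, u)
            v = V[j]
            c = (y + xi) @ Rg.T
            d = c - v
            d0 = y @ Rg.T - v
        Et = np.einsum("ri,ri->r", d, d)
        Ent = np.einsum("ri,ri->r", d0, d0)
        if binary:
            Rt = (Et <= n0sq).astype(float)
        else:
            p = smooth_reward(Et, task.n0, task.reward.T)
            Rt = (rng.random(R_real) < p).astype(float) if bernoulli else np.asarray(p)
        Rt = Rt * alive  # frozen divergent runs stop updating
        if shared:
            W += (eta * Rt)[:, None, None] * xi[:, :, None] * u[None, None, :]
        else:
            W += (eta * Rt)[:, None, None] * xi[:, :, None] * u[:, None, :]
        E[:, tt] = Et
        En[:, tt] = Ent
        Rw[:, tt] = Rt
        alive &= np.isfinite(Ent) & (Ent <= DIVERGENCE_GUARD)
    return EnsembleResult(
        E=E,
        E_noiseless=En,
        R=Rw,
        target_index=seq,
        dirs=dirs,
        n0=task.n0,
        gamma=task.gamma,
        seed=seed,
        divergent=~alive,
    )


def evaluate_generalization(
    W: Connectivity,
    gamma: float,
    test_dirs: Sequence[float] | np.ndarray,
    field: TuningField,
    n0: float | None = None,
) -> dict:
    """Frozen-weights generalization probe over a grid of test directions.

    For each test direction the noiseless error under the rotation is
    compared with the pre-adaptation noiseless error ``2 (1 - cos gamma)``
    (the same for every direction), giving the generalization value
    ``G = 1 - E_after / E_before``: 1 is perfect transfer, 0 no transfer,
    negative worse-than-baseline. If ``n0`` is given, also reports the share
    of test directions whose noiseless error lies within the target
    (test-averaged noiseless performance).

    ``gamma = 0`` leaves ``E_before = 0`` and ``G`` undefined; the result
    carries ``G=None`` with the raw errors still reported.
    """
    test_dirs = np.asarray(test_dirs, dtype=float)
    Rg = rotation_matrix(gamma)
    E_after = np.empty(len(test_dirs))
    for i, th in enumerate(test_dirs):
        u = input_activity(th, field)
        d = Rg @ (W.W @ u) - np.array([np.cos(th), np.sin(th)])
        E_after[i] = d @ d
    E_before = 2.0 * (1.0 - np.cos(gamma))
    out: dict = {"test_dirs": test_dirs, "E_after": E_after, "E_before": E_before}
    out["G"] = None if E_before == 0.0 else 1.0 - E_after / E_before
    if n0 is not None:
        out["noiseless_performance"] = float(np.mean(E_after <= n0 * n0))
    return out
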