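"""Ensemble statistics: learning durations, final errors, performance,
cross-target error correlations, delayed- and ordered-learning summaries.

The learning duration ``tau`` of an error curve is the first trial at which
the median-filtered curve (window 50 trials) drops below a threshold 5%
above the final error and stays there for a full filter window; the final
error is the median over the terminal stretch of the run. Curves that never
cross the threshold are *censored* at the run length and flagged.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .experiments import EnsembleResult, RunResult

__all__ = [
    "LearningCurveSummary",
    "final_error",
    "learning_duration",
    "linear_filter_duration",
    "summarize_curve",
    "performance_metrics",
    "cc_curve",
    "CCResult",
    "ensemble_target_durations",
    "delayed_learning_summary",
    "multitarget_summary",
    "ordered_learning_chance",
]


def final_error(errors: np.ndarray, tail_fraction: float = 0.1) -> float:
    """Median of the error over the terminal window of the run.

    The window is the last ``tail_fraction`` of the trials, widened to at
    least 10 trials (with a warning) so the median is meaningful on short
    runs.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error series")
    n_tail = int(round(tail_fraction * errors.size))
    if n_tail < 10:
        if errors.size >= 10:
            warnings.warn(
                f"terminal window of {n_tail} trials widened to 10", stacklevel=2
            )
        n_tail = min(10, errors.size)
    return float(np.median(errors[-n_tail:]))


def _median_filtered(errors: np.ndarray, window: int) -> np.ndarray:
    return ndimage.median_filter(np.asarray(errors, dtype=float), size=window, mode="nearest")


def learning_duration(
    errors: np.ndarray,
    final_err: float,
    window: int = 50,
    rel_threshold: float = 1.05,
    baseline_drop: float | None = None,
) -> tuple[int, bool]:
    """First trial at which the filtered error settles below threshold.

    Applies a running median filter of length ``window``, thresholds at
    ``rel_threshold * final_err``, and returns the first index from which
    the filtered curve stays below the threshold for at least one full
    window. Returns ``(tau, censored)``; a curve that never settles is
    censored at the run length.

    A curve that never adapts at all sits at its initial plateau, making the
    settling threshold trivially satisfied from trial 0. When
    ``baseline_drop`` is set, such curves are censored instead: the final
    error must be below ``baseline_drop`` times the initial plateau (median
    of the first filter window) for the duration to count as learning.
    """
    errors = np.asarray(errors, dtype=float)
    n = errors.size
    if n == 0:
        raise ValueError("empty error series")
    if baseline_drop is not None:
        baseline = float(np.median(errors[: min(window, n)]))
        if baseline > 0 and final_err > baseline_drop * baseline:
            return int(n), True
    filt = _median_filtered(errors, window)
    thr = rel_threshold * final_err
    below = filt <= thr
    # first run of >= window consecutive below-threshold trials (or reaching
    # the end of the series while still below)
    run = 0
    start = None
    for i in range(n):
        if below[i]:
            if run == 0:
                start = i
            run += 1
            if run >= window:
                return int(start), False
        else:
            run = 0
    if run > 0 and start is not None and start + run == n:
        # settled but the tail is shorter than a full window: accept if the
        # curve stayed below through the end
        return int(start), False
    return int(n), True


def linear_filter_duration(
    errors: np.ndarray,
    final_err: float,
    window: int = 50,
    rel_threshold: float = 1.05,
) -> tuple[int, bool]:
    """Duration estimate with a moving-average (linear) filter instead of the
    median filter; agrees with :func:`learning_duration` within the filter
    window on smooth curves and is kept as a cross-check."""
    errors = np.asarray(errors, dtype=float)
    filt = ndimage.uniform_filter1d(errors, size=window, mode="nearest")
    thr = rel_threshold * final_err
    below = filt <= thr
    n = errors.size
    run = 0
    start = None
    for i in range(n):
        if below[i]:
            if run == 0:
                start = i
            run += 1
            if run >= window:
                return int(start), False
        else:
            run = 0
    if run > 0 and start is not None and start + run == n:
        return int(start), False
    return int(n), True


@dataclass(frozen=True)
class LearningCurveSummary:
    """Scalar summary of one learning curve."""

    final_error: float
    tau: int
    censored: bool

    @property
    def log10_tau(self) -> float:
        return math.log10(self.tau) if self.tau > 0 else -math.inf


def summarize_curve(
    errors: np.ndarray,
    tail_fraction: float = 0.1,
    window: int = 50,
    rel_threshold: float = 1.05,
    baseline_drop: float | None = None,
) -> LearningCurveSummary:
    fe = final_error(errors, tail_fraction)
    tau, censored = learning_duration(errors, fe, window, rel_threshold, baseline_drop)
    return LearningCurveSummary(final_error=fe, tau=tau, censored=censored)


def performance_metrics(run: RunResult, transient: int) -> tuple[float, float]:
    """Long-run hit probabilities after the transient learning phase.

    ``performance`` is the time-averaged indicator that the noisy error lies
    within the target, ``noiseless performance`` the same for the noiseless
    error; both exclude the first ``transient`` trials and use the target
    radius in force at each trial.
    """
    if run.n_trials <= transient:
        raise ValueError("run shorter than the transient to exclude")
    n0sq = run.n0_t[transient:] ** 2
    perf = float(np.mean(run.E[transient:] <= n0sq))
    nperf = float(np.mean(run.E_noiseless[transient:] <= n0sq))
    return perf, nperf


@dataclass(frozen=True)
class CCResult:
    """Across-realization correlation between consecutive-trial errors."""

    t: np.ndarray  # trial index of the first element of each pair
    cc: np.ndarray  # raw Pearson correlation per pair position
    cc_smooth: np.ndarray  # low-passed for reporting
    cc_ext: float  # signed extremum of the smoothed curve

    def __iter__(self):
        return iter(zip(self.t, self.cc))


def _moving_average_nan(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average that ignores NaNs; shrinks at the boundaries."""
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        good = np.isfinite(seg)
        out[i] = np.mean(seg[good]) if good.any() else np.nan
    return out


def cc_curve(
    ensemble: EnsembleResult,
    j_first: int = 0,
    j_second: int = 1,
    smooth_window: int = 51,
    noiseless: bool = False,
) -> CCResult:
    """Correlation, across realizations, between the error on a trial
    presenting one target and the error on the immediately following trial
    presenting the other target.

    A negative correlation means that realizations that happen to do well on
    the first target do badly on the second — destructive interference; a
    positive one means constructive interference. Before any rewards the map
    is constant and the noise independent, so CC fluctuates around zero.

    The raw per-position correlations are low-passed with a centered moving
    average (default window 51 pair positions) for reporting; the smoothing
    shrinks at the series boundaries, so the first/last positions average
    fewer points. ``cc_ext`` is the signed extremum of the smoothed curve.
    Zero-variance positions yield NaN and are ignored by the smoother.
    """
    if ensemble.target_index.ndim != 1:
        raise ValueError("cc_curve requires a shared (cyclic) schedule")
    seq = ensemble.target_index
    E = ensemble.E_noiseless if noiseless else ensemble.E
    pair_t = np.nonzero((seq[:-1] == j_first) & (seq[1:] == j_second))[0]
    if pair_t.size == 0:
        raise ValueError("schedule contains no first->second target pairs")
    x = E[:, pair_t]  # (n_real, n_pairs)
    y = E[:, pair_t + 1]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt(np.sum(xc * xc, axis=0))
    sy = np.sqrt(np.sum(yc * yc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.sum(xc * yc, axis=0) / (sx * sy)
    cc_smooth = _moving_average_nan(cc, smooth_window)
    finite = np.isfinite(cc_smooth)
    if not finite.any():
        raise ValueError("correlation undefined everywhere (zero variance)")
    i_ext = np.nanargmax(np.abs(np.where(finite, cc_smooth, 0.0)))
    return CCResult(t=pair_t, cc=cc, cc_smooth=cc_smooth, cc_ext=float(cc_smooth[i_ext]))


def _first_sustained_below(series: np.ndarray, thr: float, window: int) -> tuple[int, bool]:
    """First index of a >= window-long run of filtered values below ``thr``."""
    filt = _median_filtered(series, window)
    below = filt <= thr
    run, start = 0, None
    for i in range(series.size):
        if below[i]:
            if run == 0:
                start = i
            run += 1
            if run >= window:
                return int(start), False
        else:
            run = 0
    if run > 0 and start is not None and start + run == series.size:
        return int(start), False
    return int(series.size), True


def ensemble_target_durations(
    ensemble: EnsembleResult,
    window: int = 50,
    tail_fraction: float = 0.1,
    criterion: str = "target",
    baseline_drop: float | None = 0.5,
) -> dict:
    """Per-realization, per-target learning durations on an ensemble.

    For each realization and each target, restricts the error series to that
    target's presentations, estimates when that target was learned, and maps
    the point back to the global trial index. Returns ``tau`` (global trial
    units), ``tau_presentations`` (per-target presentation counts),
    ``censored`` and ``final_error`` arrays of shape
    ``(n_realizations, n_targets)``.

    ``criterion="target"`` (default) marks a target learned at the first
    presentation from which its median-filtered *noiseless* error stays
    within the target (``<= n0**2``) for a full filter window — the natural
    per-target completion criterion, sharp at any noise level because the
    pre-learning noiseless error sits far above the target size.
    ``criterion="settle"`` instead applies the settling estimator
    (:func:`learning_duration`, threshold 5% above the final error) to the
    noisy error of each presentation series, censoring never-adapted targets
    through ``baseline_drop``.
    """
    if criterion not in ("target", "settle"):
        raise ValueError("criterion must be 'target' or 'settle'")
    m = len(ensemble.dirs)
    R = ensemble.n_realizations
    E = ensemble.E_noiseless if criterion == "target" else ensemble.E
    thr = ensemble.n0 ** 2
    shared = ensemble.target_index.ndim == 1
    tau = np.empty((R, m), dtype=int)
    tau_pres = np.empty((R, m), dtype=int)
    censored = np.zeros((R, m), dtype=bool)
    fe = np.empty((R, m))
    for j in range(m):
        if shared:
            idx = np.nonzero(ensemble.target_index == j)[0]
        for r in range(R):
            if not shared:
                idx = np.nonzero(ensemble.target_index[r] == j)[0]
            series = E[r, idx]
            fe[r, j] = final_error(series, tail_fraction)
            if criterion == "target":
                tp, cens = _first_sustained_below(series, thr, window)
            else:
                tp, cens = learning_duration(
                    series, fe[r, j], window=window, baseline_drop=baseline_drop
                )
            censored[r, j] = cens
            tau_pres[r, j] = tp
            tau[r, j] = idx[min(tp, len(idx) - 1)] if not cens else ensemble.n_trials
    return {"tau": tau, "tau_presentations": tau_pres, "censored": censored, "final_error": fe}


def delayed_learning_summary(
    tau_two_target: np.ndarray,
    censored: np.ndarray,
    tau_single: np.ndarray,
) -> dict:
    """Order statistics of the two per-target durations vs an independence null.

    ``tau_two_target`` is ``(n_real, 2)``; per realization, ``tau1 <= tau2``
    are the sorted per-target durations and ``ratio = tau2 / tau1`` measures
    the lag of the slower target. The null hypothesis of independent,
    non-interacting learning predicts that ``tau2`` is distributed like the
    maximum of two independent draws from the single-target duration
    distribution at matched parameters; the summary reports that null's
    empirical distribution alongside the observed ``tau2``.

    Realizations with a censored duration are excluded from the ratio
    statistics (the ratio would be a lower bound) but counted.
    """
    tau_two_target = np.asarray(tau_two_target, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    any_cens = censored.any(axis=1)
    pairs = np.sort(tau_two_target, axis=1)
    tau1, tau2 = pairs[:, 0], pairs[:, 1]
    ok = ~any_cens & (tau1 > 0)
    ratio = tau2[ok] / tau1[ok]
    tau_single = np.asarray(tau_single, dtype=float)
    rng_pairs = tau_single[None, :], tau_single[:, None]
    null_max = np.maximum(rng_pairs[0], rng_pairs[1]).ravel()
    null_min = np.minimum(rng_pairs[0], rng_pairs[1]).ravel()
    return {
        "tau1": tau1,
        "tau2": tau2,
        "ratio": ratio,
        "median_ratio": float(np.median(ratio)) if ratio.size else math.nan,
        "n_censored": int(any_cens.sum()),
        "null_max": null_max,
        "null_min": null_min,
        "median_tau2": float(np.median(tau2[ok])) if ok.any() else math.nan,
        "median_null_max": float(np.median(null_max)),
    }


def ordered_learning_chance(m: int) -> float:
    """Chance probability of a close-to-far completion order for ``m`` evenly
    spaced targets.

    Given the first-completed target, the remaining ``m - 1`` targets fall
    into angular-distance groups (symmetric clockwise/counter-clockwise
    distances are tied and exchangeable). The chance level is the fraction
    of the ``(m-1)!`` completion orders whose distance sequence is
    non-decreasing, computed by exact enumeration.
    """
    if m < 2:
        return 1.0
    dists = [min(k, m - k) for k in range(1, m)]
    n_ordered = sum(
        1
        for perm in itertools.permutations(dists)
        if all(perm[i] <= perm[i + 1] for i in range(len(perm) - 1))
    )
    return n_ordered / math.factorial(m - 1)


def _is_close_to_far(tau_row: np.ndarray, m: int) -> bool:
    """A realization is 'ordered' if completion times are non-decreasing in
    angular distance from the first-completed target (distance ties
    exchangeable)."""
    j0 = int(np.argmin(tau_row))
    dist = np.minimum((np.arange(m) - j0) % m, (j0 - np.arange(m)) % m)
    order = np.argsort(tau_row, kind="stable")
    d_seq = dist[order]
    return bool(np.all(np.diff(d_seq) >= 0))


def multitarget_summary(tau: np.ndarray, censored: np.ndarray) -> dict:
    """Entire-task duration and ordered-learning statistics for ``m`` targets.

    ``tau`` is ``(n_real, m)`` in global trial (total presentation) units.
    The entire-task duration of a realization is the trial at which the last
    per-target criterion is met; the ordered fraction is the share of
    (uncensored) realizations completing in close-to-far order, reported
    next to the exact chance level.
    """
    tau = np.asarray(tau)
    censored = np.asarray(censored, dtype=bool)
    m = tau.shape[1]
    ok = ~censored.any(axis=1)
    entire = tau[ok].max(axis=1) if ok.any() else np.array([], dtype=tau.dtype)
    ordered = (
        np.array([_is_close_to_far(row, m) for row in tau[ok]])
        if ok.any()
        else np.array([], dtype=bool)
    )
    return {
        "entire_task_duration": entire,
        "mean_entire_task_duration": float(np.mean(entire)) if entire.size else math.nan,
        "ordered_fraction": float(np.mean(ordered)) if ordered.size else math.nan,
        "chance_level": ordered_learning_chance(m),
        "n_censored": int((~ok).sum()),
    }
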