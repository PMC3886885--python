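"""Tests of the trial loop: reward families, schedules, shaping controllers,
determinism, and the generalization probe."""

import numpy as np
import pytest

from rotadapt.experiments import (
    DIVERGENCE_GUARD,
    RewardSpec,
    ScheduleSpec,
    ShapingSpec,
    TaskSpec,
    evaluate_generalization,
    reward_value,
    run_adaptation,
    run_ensemble,
    smooth_reward,
)
from rotadapt.model import LearningSpec, NoiseSpec, init_connectivity
from rotadapt import analytics as an

from conftest import E0_30, GAMMA30


def make_task(field, n0=0.15, gamma=GAMMA30, reward=RewardSpec()):
    return TaskSpec(field=field, gamma=gamma, n0=n0, reward=reward)


class TestRewardFamilies:
    def test_smooth_reward_is_half_at_boundary(self):
        spec = RewardSpec(family="smooth_deterministic", T=0.01)
        assert reward_value(0.15**2, spec, 0.15) == pytest.approx(0.5)

    def test_smooth_reward_recovers_binary_in_sharp_limit(self):
        spec = RewardSpec(family="smooth_deterministic", T=1e-9)
        for E in (0.001, 0.01, 0.05, 0.5):
            assert reward_value(E, spec, 0.15) == pytest.approx(
                float(E <= 0.15**2), abs=1e-12
            )

    def test_bernoulli_success_rate_matches_logistic(self):
        spec = RewardSpec(family="stochastic_bernoulli", T=0.02)
        rng = np.random.default_rng(7)
        E, n0 = 0.03, 0.15
        p = smooth_reward(E, n0, 0.02)
        n = 100_000
        draws = np.array([reward_value(E, spec, n0, rng) for _ in range(n)])
        se = np.sqrt(p * (1 - p) / n)
        assert draws.mean() == pytest.approx(p, abs=3 * se)

    def test_nonbinary_family_requires_positive_smoothing(self):
        with pytest.raises(ValueError, match="T > 0"):
            RewardSpec(family="smooth_deterministic", T=0.0)

    def test_bernoulli_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            reward_value(0.1, RewardSpec(family="stochastic_bernoulli", T=0.1), 0.1)


class TestScheduleSpec:
    def test_default_directions_evenly_spaced(self):
        dirs = ScheduleSpec(m=4).directions()
        assert np.allclose(np.diff(dirs), np.pi / 2)

    def test_cyclic_alternation(self):
        seq = ScheduleSpec(m=2).sequence(6, np.random.default_rng(0))
        assert list(seq) == [0, 1, 0, 1, 0, 1]

    def test_random_uniform_covers_targets(self):
        seq = ScheduleSpec(m=3, mode="random_uniform").sequence(3000, np.random.default_rng(1))
        counts = np.bincount(seq, minlength=3)
        assert np.all(counts > 800)


class TestRunAdaptation:
    def test_noise_free_unrotated_run_is_static(self, field60):
        """sigma = 0 and gamma = 0: zero error, full reward, no weight drift."""
        task = make_task(field60, gamma=0.0)
        run = run_adaptation(
            task, ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.0),
            LearningSpec.from_eta_tilde(0.5, field60), 200, seed=0,
        )
        assert np.all(run.E < 1e-20)
        assert np.all(run.R == 1.0)
        assert np.array_equal(run.W_final.W, init_connectivity(field60).W)

    def test_replay_is_bit_identical(self, field60):
        task = make_task(field60)
        args = (task, ScheduleSpec(m=2), ShapingSpec(), NoiseSpec(0.3),
                LearningSpec.from_eta_tilde(0.5, field60), 500)
        a = run_adaptation(*args, seed=42)
        b = run_adaptation(*args, seed=42)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.R, b.R)
        assert np.array_equal(a.W_final.W, b.W_final.W)

    def test_different_seeds_give_independent_noise(self, field60):
        task = make_task(field60)
        args = (task, ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.3),
                LearningSpec.from_eta_tilde(0.0, field60), 2000)
        a = run_adaptation(*args, seed=1)
        b = run_adaptation(*args, seed=2)
        r = np.corrcoef(a.E, b.E)[0, 1]
        assert abs(r) < 0.08

    def test_weights_frozen_before_first_reward(self, field60):
        task = make_task(field60, n0=0.05)
        run = run_adaptation(
            task, ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.1),
            LearningSpec.from_eta_tilde(0.5, field60), 3000, seed=3,
        )
        first = np.nonzero(run.R > 0)[0]
        prefix = run.E_noiseless[: (first[0] + 1)] if first.size else run.E_noiseless
        assert np.allclose(prefix, prefix[0])

    def test_rotated_initial_error_convention(self, field60):
        """Trial 0 is evaluated with the rotation already in force."""
        run = run_adaptation(
            make_task(field60), ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.0),
            LearningSpec.from_eta_tilde(0.5, field60), 1, seed=0,
        )
        assert run.E_noiseless[0] == pytest.approx(E0_30, abs=1e-10)

    def test_divergent_run_flagged_and_truncated(self, field60):
        """With a reward that never decays (flat logistic) and a huge rate the
        map performs an unbounded random walk and trips the guard. With the
        binary reward a runaway self-limits instead: far from the target
        rewards stop arriving and the map freezes."""
        task = make_task(
            field60, n0=0.3, reward=RewardSpec(family="smooth_deterministic", T=1e6)
        )
        run = run_adaptation(
            task, ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.5),
            LearningSpec.from_eta_tilde(50.0, field60), 20000, seed=4,
        )
        assert run.divergent
        assert run.n_trials < 20000
        assert run.E_noiseless[-1] > DIVERGENCE_GUARD

    def test_higher_noise_earlier_rewards_with_larger_targets(self, field60):
        """With a biggish target, more output noise brings the first reward
        earlier and still lets the median late error settle under threshold."""
        task = make_task(field60, n0=0.3)
        spec = ScheduleSpec(m=1)
        first_rewards, late_medians = {}, {}
        for sigma in (0.1, 0.3):
            firsts = []
            lates = []
            for seed in range(10):
                run = run_adaptation(
                    task, spec, ShapingSpec(), NoiseSpec(sigma),
                    LearningSpec.from_eta_tilde(0.5, field60), 4000, seed=seed,
                )
                rewarded = np.nonzero(run.R > 0)[0]
                firsts.append(rewarded[0] if rewarded.size else 4000)
                lates.append(np.median(run.E_noiseless[-400:]))
            first_rewards[sigma] = np.median(firsts)
            late_medians[sigma] = np.median(lates)
        assert first_rewards[0.3] < first_rewards[0.1]
        assert late_medians[0.3] < 0.3**2

    def test_destructive_interference_raises_other_targets_error(self, field60):
        """Opposite targets, low noise: the lagging target's noiseless error
        transiently exceeds its initial value once the first target's rewards
        begin."""
        task = make_task(field60, n0=0.15)
        run = run_adaptation(
            task, ScheduleSpec(m=2), ShapingSpec(), NoiseSpec(0.18),
            LearningSpec.from_eta_tilde(0.5, field60), 4000, seed=31,
        )
        # the slower target is whichever still has a large error at the end of
        # the window; its peak must overshoot the initial error
        peaks = []
        for j in (0, 1):
            _, e = run.target_series(j)
            peaks.append(e.max())
        assert max(peaks) > E0_30 * 1.2


class TestShaping:
    def test_noop_at_final_target_size(self, field60):
        shaping = ShapingSpec(kind="target_size", n0_init=0.1, n0_step=0.05, n0_final=0.1,
                              ema_timescale=20.0, steady_tol=0.5)
        run = run_adaptation(
            make_task(field60, n0=0.1), ScheduleSpec(m=1), shaping, NoiseSpec(0.3),
            LearningSpec.from_eta_tilde(0.5, field60), 500, seed=0,
        )
        assert np.all(run.n0_t == 0.1)

    def test_target_size_curriculum_beats_unshaped(self, field60):
        """At very low noise the final target is unreachable from scratch, but
        the shrinking-target curriculum reaches it with a high reward rate."""
        task = make_task(field60, n0=0.05)
        shaping = ShapingSpec(kind="target_size", n0_init=0.6, n0_step=0.05,
                              n0_final=0.05, ema_timescale=40.0, steady_tol=0.05)
        args = (ScheduleSpec(m=1), NoiseSpec(0.03), LearningSpec.from_eta_tilde(0.5, field60))
        shaped = run_adaptation(task, args[0], shaping, args[1], args[2], 2000, seed=303)
        unshaped = run_adaptation(task, args[0], ShapingSpec(), args[1], args[2], 2000, seed=303)
        assert shaped.n0_t[-1] == pytest.approx(0.05)
        assert shaped.R[-200:].mean() > 0.5
        assert unshaped.R.sum() == 0

    def test_gradual_rotation_tracks_large_angle(self, field60):
        """Stepping the rotation to 90 degrees block-by-block succeeds in most
        seeds within a small multiple of the nominal schedule length."""
        task = make_task(field60, n0=0.15, gamma=np.deg2rad(90.0))
        shaping = ShapingSpec(kind="rotation_angle", gamma_step=np.deg2rad(7.5), block_len=25)
        successes = 0
        for seed in range(8):
            run = run_adaptation(
                task, ScheduleSpec(m=1), shaping, NoiseSpec(0.2),
                LearningSpec.from_eta_tilde(0.5, field60), 2000, seed=seed,
            )
            assert run.gamma_t[-1] == pytest.approx(np.deg2rad(90.0))
            if np.median(run.E_noiseless[-100:]) <= 0.15**2:
                successes += 1
        assert successes >= 6

    def test_shaping_transitions_recorded(self, field60):
        shaping = ShapingSpec(kind="rotation_angle", gamma_step=np.deg2rad(10.0), block_len=25)
        run = run_adaptation(
            make_task(field60, gamma=np.deg2rad(30.0)), ScheduleSpec(m=1), shaping,
            NoiseSpec(0.2), LearningSpec.from_eta_tilde(0.5, field60), 200, seed=0,
        )
        assert [t for t, _, _ in run.shaping_transitions] == [25, 50, 75]
        assert run.gamma_t[0] == 0.0


class TestEnsemble:
    def test_matches_requested_shape_and_determinism(self, field60):
        task = make_task(field60)
        args = (task, ScheduleSpec(m=2), NoiseSpec(0.3), LearningSpec.from_eta_tilde(0.5, field60), 300, 20)
        a = run_ensemble(*args, seed=9)
        b = run_ensemble(*args, seed=9)
        assert a.E.shape == (20, 300)
        assert np.array_equal(a.E, b.E)

    def test_ensemble_statistics_match_single_runs(self, field60):
        """The vectorized engine and the per-run loop agree statistically."""
        task = make_task(field60, n0=0.2)
        noise, learning = NoiseSpec(0.3), LearningSpec.from_eta_tilde(0.5, field60)
        ens = run_ensemble(task, ScheduleSpec(m=1), noise, learning, 2000, 60, seed=10)
        late_ens = np.median(ens.E_noiseless[:, -200:])
        singles = [
            run_adaptation(task, ScheduleSpec(m=1), ShapingSpec(), noise, learning, 2000,
                           seed=11, realization=i).E_noiseless[-200:]
            for i in range(20)
        ]
        late_single = np.median(np.concatenate(singles))
        assert late_ens == pytest.approx(late_single, abs=0.01)


class TestGeneralizationProbe:
    def test_trained_direction_recovers_after_convergence(self, field60):
        task = make_task(field60, n0=0.05)
        run = run_adaptation(
            task, ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.2),
            LearningSpec.from_eta_tilde(0.1, field60), 30000, seed=37,
        )
        res = evaluate_generalization(run.W_final, GAMMA30, [0.0], field60, n0=0.05)
        assert res["G"][0] > 0.97

    def test_weight_norm_returns_after_single_target_convergence(self, field60):
        task = make_task(field60, n0=0.05)
        run = run_adaptation(
            task, ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.2),
            LearningSpec.from_eta_tilde(0.1, field60), 30000, seed=37,
        )
        w0 = init_connectivity(field60).frobenius_norm
        assert run.W_final.frobenius_norm == pytest.approx(w0, rel=0.05)

    def test_three_targets_generalize_almost_everywhere_broad_tuning(self, field60):
        """Adapting to 3 evenly spaced targets suffices for near-perfect
        noiseless performance on a dense test grid (broad tuning)."""
        task = make_task(field60, n0=0.15)
        run = run_adaptation(
            task, ScheduleSpec(m=3, mode="random_uniform"), ShapingSpec(), NoiseSpec(0.2),
            LearningSpec.from_eta_tilde(0.5, field60), 30000, seed=12,
        )
        test_dirs = np.deg2rad(np.arange(0, 360, 5.0))
        res = evaluate_generalization(run.W_final, GAMMA30, test_dirs, field60, n0=0.15)
        assert res["noiseless_performance"] > 0.95

    def test_profile_matches_closed_form(self, field60):
        task = make_task(field60, n0=0.05)
        run = run_adaptation(
            task, ScheduleSpec(m=1), ShapingSpec(), NoiseSpec(0.2),
            LearningSpec.from_eta_tilde(0.1, field60), 30000, seed=37,
        )
        test = np.deg2rad(np.arange(0, 360, 15.0))
        res = evaluate_generalization(run.W_final, GAMMA30, test, field60)
        G_th = an.generalization_curve(test, field60)
        assert np.mean(np.abs(res["G"] - G_th)) < 0.05

    def test_undefined_without_rotation(self, field60):
        res = evaluate_generalization(init_connectivity(field60), 0.0, [0.3], field60)
        assert res["G"] is None and res["E_before"] == 0.0
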