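"""Plant dynamics, demonstrator policy, EMG synthesis and calibration."""

import numpy as np
import pytest

from tkebgc import synth
from tkebgc.data import GESTURES
from tkebgc.synth import (
    DemonstratorConfig,
    PlantState,
    SYNERGY,
    TaskConfig,
    demonstrator_policy,
    initial_state,
    simulate_demonstration,
    step_environment,
    synthesize_emg,
    synthesize_gesture_trial,
    task_config,
)


def closed_state(total_force_target=8.0):
    """A plant state holding the tool at roughly the target force."""
    # closure c with all pads engaged: F = k * (9c - sum(thresholds))
    k = synth.PAD_STIFFNESS[0]
    c = (total_force_target / k + synth.PAD_THRESHOLDS_DEG.sum()) / 9.0
    joints = np.full(5, c)  # synergy sums to 1, so closure == c
    state = PlantState(joints=joints, has_grasped=True)
    state.contact_forces = synth._pad_forces(c, 0.0)
    return state


def run_episode(task, seed, ticks=1200, freeze_after=120):
    """Demonstrator episode; freeze_after=None keeps corrections active."""
    cfg = task_config(task, episode_ticks=ticks, seed=seed)
    demo = DemonstratorConfig()
    state = initial_state()
    forces = [state.total_force]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)).spawn(2)[0])
    band = 0
    for t in range(ticks):
        if freeze_after is not None and t >= freeze_after:
            dj = np.zeros(5)
        else:
            dj = demonstrator_policy(forces, demo, joints=state.joints)
        state = step_environment(state, dj, cfg, rng)
        f = state.contact_forces
        if f.sum() > 0.1 and f.max() <= 15.0:
            band += 1
        forces.append(state.total_force)
    return state.n_drops, band / ticks


class TestStepEnvironment:
    def test_equilibrium_is_a_fixed_point_without_impacts(self):
        cfg = TaskConfig(task="desk", impact_amplitude=1e-9, impact_rate=1e-9,
                         episode_ticks=10)
        state = closed_state()
        rng = np.random.default_rng(0)
        nxt = step_environment(state, np.zeros(5), cfg, rng)
        np.testing.assert_allclose(nxt.joints, state.joints)
        np.testing.assert_allclose(nxt.contact_forces, state.contact_forces, atol=1e-9)
        assert nxt.n_drops == 0

    def test_same_seed_gives_identical_trajectories(self):
        cfg = task_config("hammer", episode_ticks=50, seed=3)
        for _ in range(2):
            rngs = [np.random.default_rng(9), np.random.default_rng(9)]
            states = [closed_state(), closed_state()]
            for t in range(50):
                states = [step_environment(s, np.full(5, 0.1), cfg, r)
                          for s, r in zip(states, rngs)]
            np.testing.assert_array_equal(states[0].joints, states[1].joints)
            np.testing.assert_array_equal(states[0].contact_forces,
                                          states[1].contact_forces)

    def test_closing_without_disturbance_gives_nondecreasing_force(self):
        cfg = TaskConfig(task="desk", impact_amplitude=1e-9, impact_rate=1e-9,
                         episode_ticks=100)
        state = initial_state()
        rng = np.random.default_rng(0)
        prev = state.total_force
        for _ in range(60):
            state = step_environment(state, np.full(5, 2.0), cfg, rng)
            assert state.total_force >= prev - 1e-9
            prev = state.total_force
        assert prev > 5.0

    def test_forces_stay_in_sensor_range(self):
        cfg = task_config("hammer", episode_ticks=300, seed=1)
        state = initial_state()
        rng = np.random.default_rng(1)
        for _ in range(300):
            state = step_environment(state, np.full(5, 5.0), cfg, rng)
            assert np.all(state.contact_forces >= 0)
            assert np.all(state.contact_forces <= 20.0)

    def test_non_finite_command_rejected(self):
        cfg = task_config("desk", episode_ticks=5)
        with pytest.raises(synth.ControlError):
            step_environment(initial_state(), np.array([np.nan] * 5), cfg,
                             np.random.default_rng(0))


class TestDemonstratorPolicy:
    def test_zero_error_at_reference_posture_gives_zero_correction(self):
        cfg = DemonstratorConfig()
        closure = 50.0
        joints = closure * SYNERGY / float(SYNERGY @ SYNERGY)
        dj = demonstrator_policy([cfg.target_force], cfg, joints=joints)
        np.testing.assert_allclose(dj, 0.0, atol=1e-9)

    def test_force_deficit_gives_positive_closing_correction(self):
        cfg = DemonstratorConfig()
        dj = demonstrator_policy([cfg.target_force - 2.0], cfg)
        assert np.all(dj > 0)
        np.testing.assert_allclose(dj, np.clip(cfg.gain * 2.0 * SYNERGY, -5, 5))

    def test_reaction_delay_bookkeeping(self):
        cfg = DemonstratorConfig(reaction_delay_ticks=3)
        # force drops at the last tick; with delay 3 the policy still sees 8 N
        history = [8.0, 8.0, 8.0, 8.0, 2.0]
        np.testing.assert_allclose(demonstrator_policy(history, cfg), 0.0, atol=1e-12)
        # once the drop is 3 ticks old, the correction appears
        history = [8.0, 2.0, 2.0, 2.0, 2.0]
        assert np.all(demonstrator_policy(history, cfg) > 0)

    def test_posture_term_restores_in_null_space(self):
        cfg = DemonstratorConfig()
        closure = 50.0
        ref = closure * SYNERGY / float(SYNERGY @ SYNERGY)
        perturbed = ref + np.array([2.0, -1.0, 1.0, 0.0, -2.0 * 0.1 / 0.1])
        perturbed += (closure - SYNERGY @ perturbed) * SYNERGY / (SYNERGY @ SYNERGY)
        dj = demonstrator_policy([cfg.target_force], cfg, joints=perturbed)
        # pure posture correction: no net closure change
        assert abs(float(SYNERGY @ dj)) < 1e-9
        assert np.linalg.norm(dj) > 0


class TestEmgSynthesis:
    def test_zero_effort_without_noise_is_silent(self):
        cfg = DemonstratorConfig(emg_noise_sd=0.0)
        x = synthesize_emg(np.zeros(30), cfg, rng=np.random.default_rng(0))
        assert np.abs(x).max() == 0.0

    def test_envelope_grows_monotonically_with_effort(self):
        cfg = DemonstratorConfig(emg_noise_sd=0.0)
        levels = [0.2, 0.5, 1.0, 1.5, 2.0]
        means = [
            np.abs(synthesize_emg(np.full(60, lv), cfg,
                                  rng=np.random.default_rng(4))).mean()
            for lv in levels
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_values_respect_sensor_range(self):
        cfg = DemonstratorConfig(emg_gain=5.0, emg_noise_sd=1.0)
        x = synthesize_emg(np.full(120, 3.0), cfg, rng=np.random.default_rng(2))
        assert np.abs(x).max() <= 2.0

    def test_negative_effort_rejected(self):
        with pytest.raises(ValueError):
            synthesize_emg(np.array([-1.0]), DemonstratorConfig())


class TestSimulateDemonstration:
    def test_identical_seeds_give_bit_identical_trials(self):
        cfg = task_config("saw", episode_ticks=200, seed=11)
        a = simulate_demonstration(cfg, repetition=2)
        b = simulate_demonstration(cfg, repetition=2)
        np.testing.assert_array_equal(a.emg, b.emg)
        np.testing.assert_array_equal(a.tactile, b.tactile)
        np.testing.assert_array_equal(a.joints, b.joints)

    def test_trial_passes_container_validation(self):
        trial = simulate_demonstration(task_config("hammer", episode_ticks=200, seed=0))
        assert trial.n_ticks == 200
        assert trial.emg.shape == (200, 3)
        assert trial.tactile.shape == (200, 9)


@pytest.fixture(scope="module")
def drop_stats():
    stats = {}
    for task in ("hammer", "saw", "peel", "desk"):
        frozen = [run_episode(task, s, freeze_after=120)[0] for s in range(20)]
        corrected = [run_episode(task, s, freeze_after=None) for s in range(20)]
        stats[task] = {
            "frozen_drops": np.mean(frozen),
            "frozen_any": np.mean([d >= 1 for d in frozen]),
            "demo_drops": np.mean([c[0] for c in corrected]),
            "band": np.mean([c[1] for c in corrected]),
        }
    return stats


class TestCalibration:
    """Generator acceptance requirements on drop statistics and band time."""

    def test_corrective_demonstrator_never_drops_on_gentle_tasks(self, drop_stats):
        assert drop_stats["peel"]["demo_drops"] == 0.0
        assert drop_stats["desk"]["demo_drops"] == 0.0

    def test_frozen_policy_drops_under_hammer_impacts(self, drop_stats):
        assert drop_stats["hammer"]["frozen_any"] >= 0.5

    def test_disturbance_ordering_of_frozen_drop_counts(self, drop_stats):
        s = drop_stats
        assert s["hammer"]["frozen_drops"] >= s["saw"]["frozen_drops"]
        assert s["saw"]["frozen_drops"] >= s["peel"]["frozen_drops"]
        assert s["saw"]["frozen_drops"] >= s["desk"]["frozen_drops"]

    def test_demonstrator_keeps_ideal_band_on_gentle_tasks(self, drop_stats):
        assert drop_stats["peel"]["band"] >= 0.90
        assert drop_stats["desk"]["band"] >= 0.90


class TestGestureTrials:
    def test_native_sample_count(self):
        x = synthesize_gesture_trial("HG", duration_s=10.0,
                                     rng=np.random.default_rng(0))
        assert x.shape == (20000, 3)

    def test_rest_is_at_noise_floor(self):
        rng = np.random.default_rng(0)
        rest = np.abs(synthesize_gesture_trial("RE", 2.0, rng=rng)).mean(axis=0)
        active = np.abs(synthesize_gesture_trial("HG", 2.0, rng=rng)).mean(axis=0)
        assert np.all(rest < 0.1)
        assert active.max() > 3 * rest.max()

    def test_gesture_centroids_are_separable(self):
        rng = np.random.default_rng(5)
        noise_sd = 0.05
        cents = {
            g: np.abs(synthesize_gesture_trial(g, 2.0, noise_sd=noise_sd, rng=rng)).mean(axis=0)
            for g in GESTURES
        }
        labels = list(cents)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert np.linalg.norm(cents[a] - cents[b]) > 3 * noise_sd

    def test_unknown_gesture_rejected(self):
        with pytest.raises(ValueError):
            synthesize_gesture_trial("XX", 1.0)
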