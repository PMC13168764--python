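"""Synthetic grasp dynamics, demonstrator policy, and EMG synthesis.

This module plays two roles: it generates demonstration trials with the
statistical structure the imitation-learned controller assumes (EMG envelope
tracks effort, contact forces follow a compliant contact model, rigid
impacts perturb the grip, a demonstrator applies delayed corrective joint
increments), and it serves as the closed-loop plant for controller
evaluation.

Plant model
-----------
Grip closure is the synergy-weighted joint angle ``c = s . J`` (degrees).
A rigid tool seated in the hand can slip outward by ``tool_displacement``
(mm; 1 mm of displacement costs 1 degree of effective closure).  Each of the
9 tactile pads is a linear spring engaging at a staggered closure threshold:

    F_i = clip(k_i * max(0, c - disp - theta_i), 0, 20 N)

Impacts arrive as a Poisson process and kick the displacement outward.
Whenever total normal force falls below the friction-cone requirement
``m g / mu`` the tool slips (displacement ratchets up at a rate proportional
to the force deficit); otherwise displacement decays back as the tool
re-seats.  A drop is registered when all pads read <= 0.1 N for a debounce
horizon; the dropped tool is recovered (re-seated) after a fixed penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .data import MultimodalTrial, TrialMeta, GESTURES

__all__ = [
    "TaskConfig",
    "PlantState",
    "DemonstratorConfig",
    "task_config",
    "initial_state",
    "step_environment",
    "demonstrator_policy",
    "synthesize_emg",
    "simulate_demonstration",
    "synthesize_gesture_trial",
    "SYNERGY",
    "PAD_THRESHOLDS_DEG",
    "PAD_STIFFNESS",
]

TICK_RATE = 60.0
N_JOINTS = 5
N_PADS = 9
MAX_STEP_DEG = 5.0           # per-tick joint increment clamp
JOINT_LIMITS = (0.0, 90.0)
PAD_SAT_N = 20.0
DROP_FORCE_N = 0.1           # "all pads <= 0.1 N" drop threshold
DROP_DEBOUNCE_TICKS = 3
RECOVERY_TICKS = 60          # 1 s to pick the tool back up after a drop
GRAVITY = 9.81

# Fixed flexion synergy: middle joints dominate grip corrections.
SYNERGY = np.array([0.1, 0.3, 0.3, 0.2, 0.1])

# Pads engage sequentially as the hand closes; stiffness set so that full
# closure (c = 90 deg) yields ~18 N total across the 9 pads.
PAD_THRESHOLDS_DEG = np.linspace(20.0, 44.0, N_PADS)
PAD_STIFFNESS = np.full(N_PADS, 18.0 / float(np.sum(90.0 - PAD_THRESHOLDS_DEG)))

SLIP_RATE_MM_PER_TICK = 1.5
DISP_DECAY_PER_TICK = 0.80
EMG_FS_HZ = 2000.0


class ControlError(ValueError):
    pass


@dataclass(frozen=True)
class TaskConfig:
    task: str = "desk"
    impact_amplitude: float = 1.0   # mm of displacement kicked per impact
    impact_rate: float = 0.3        # impact events per second
    load_mass: float = 0.5          # kg
    friction_mu: float = 0.8
    episode_ticks: int = 1800
    seed: int = 0

    def __post_init__(self):
        if min(self.impact_amplitude, self.impact_rate, self.load_mass,
               self.friction_mu) <= 0 or self.episode_ticks < 1:
            raise ValueError("all physical quantities must be positive")

    @property
    def slip_threshold_n(self) -> float:
        """Minimum total normal force holding the tool (friction cone)."""
        return self.load_mass * GRAVITY / self.friction_mu


# Disturbance calibration: hammering transmits the strongest rigid impacts,
# sawing intermediate, peeling and desk organisation only light contact.
_TASK_PRESETS: dict[str, dict] = {
    "hammer": dict(impact_amplitude=8.0, impact_rate=1.2),
    "saw": dict(impact_amplitude=4.0, impact_rate=1.0),
    "peel": dict(impact_amplitude=1.0, impact_rate=0.6),
    "desk": dict(impact_amplitude=1.0, impact_rate=0.4),
}


def task_config(task: str, episode_ticks: int = 1800, seed: int = 0, **overrides) -> TaskConfig:
    if task not in _TASK_PRESETS:
        raise ValueError(f"unknown task {task!r}")
    kw = dict(_TASK_PRESETS[task])
    kw.update(overrides)
    return TaskConfig(task=task, episode_ticks=episode_ticks, seed=seed, **kw)


@dataclass
class PlantState:
    joints: np.ndarray                       # [N_J] degrees
    tool_displacement: float = 0.0           # mm outward slip (0 = seated)
    contact_forces: np.ndarray = field(default_factory=lambda: np.zeros(N_PADS))
    slip_flag: bool = False
    tick: int = 0
    # drop bookkeeping; a drop can only occur after the tool was grasped
    has_grasped: bool = False
    unsuccessful_streak: int = 0
    n_drops: int = 0
    recovery_left: int = 0

    @property
    def total_force(self) -> float:
        return float(self.contact_forces.sum())


@dataclass(frozen=True)
class DemonstratorConfig:
    target_force: float = 8.0        # N, inside the ideal 0.1-15 N band
    gain: float = 4.0                # degrees per newton of force error
    # The demonstrator corrects against the latest force reading (delay 0);
    # one tick of loop latency remains inherent in the plant update, and
    # sensor-pipeline delay is what distinguishes the FoF baseline.
    reaction_delay_ticks: int = 0
    # Humans also keep a comfortable grip posture: a weak pull of the joints
    # toward the synergy-proportional posture at the current closure.  The
    # term lies in the null space of the closure map, so it never fights the
    # force correction, but it keeps demonstrations (and any policy cloned
    # from them) on a stable posture manifold.
    posture_gain: float = 0.3        # per-tick fraction of posture error
    emg_gain: float = 0.35           # mV of envelope per unit effort
    emg_noise_sd: float = 0.04       # mV baseline noise on the envelope

    def __post_init__(self):
        if self.gain <= 0 or self.reaction_delay_ticks < 0:
            raise ValueError("gain must be positive, delay >= 0")
        if not (DROP_FORCE_N < self.target_force < 15.0):
            raise ValueError("target force must lie inside the (0.1, 15) N band")


def _pad_forces(closure: float, displacement: float) -> np.ndarray:
    eff = closure - displacement
    return np.clip(PAD_STIFFNESS * np.maximum(0.0, eff - PAD_THRESHOLDS_DEG), 0.0, PAD_SAT_N)


def initial_state(open_angle_deg: float = 10.0) -> PlantState:
    j = np.full(N_JOINTS, open_angle_deg)
    return PlantState(joints=j, contact_forces=_pad_forces(float(SYNERGY @ j), 0.0))


def step_environment(
    state: PlantState,
    dj_command: np.ndarray,
    cfg: TaskConfig,
    rng: np.random.Generator,
) -> PlantState:
    """Advance the plant one control tick under a joint-increment command."""
    dj = np.asarray(dj_command, dtype=float)
    if not np.all(np.isfinite(dj)):
        raise ControlError("joint command contains non-finite values")
    dj = np.clip(dj, -MAX_STEP_DEG, MAX_STEP_DEG)
    joints = np.clip(state.joints + dj, *JOINT_LIMITS)

    disp = state.tool_displacement
    n_drops = state.n_drops
    streak = state.unsuccessful_streak
    recovery = state.recovery_left
    grasped = state.has_grasped
    slip = False

    if recovery > 0:
        # tool on the floor; hand follows commands but nothing to squeeze
        recovery -= 1
        if recovery == 0:
            disp = 0.0  # re-seated
        forces = np.zeros(N_PADS)
        streak = 0
    else:
        closure = float(SYNERGY @ joints)
        if grasped:
            # impacts and slip act only on a tool that is actually held
            dt = 1.0 / TICK_RATE
            n_impacts = rng.poisson(cfg.impact_rate * dt)
            for _ in range(n_impacts):
                disp += cfg.impact_amplitude * (0.75 + 0.5 * rng.random())
            total = float(_pad_forces(closure, disp).sum())
            if total < cfg.slip_threshold_n:
                slip = True
                deficit = (cfg.slip_threshold_n - total) / cfg.slip_threshold_n
                disp += SLIP_RATE_MM_PER_TICK * deficit
            else:
                disp *= DISP_DECAY_PER_TICK
        forces = _pad_forces(closure, disp)
        if forces.sum() >= 1.0:
            grasped = True
        if grasped and np.all(forces <= DROP_FORCE_N):
            streak += 1
            if streak >= DROP_DEBOUNCE_TICKS:
                n_drops += 1
                streak = 0
                grasped = False
                recovery = RECOVERY_TICKS
                forces = np.zeros(N_PADS)
        else:
            streak = 0

    return PlantState(
        joints=joints,
        tool_displacement=disp,
        contact_forces=forces,
        slip_flag=slip,
        tick=state.tick + 1,
        has_grasped=grasped,
        unsuccessful_streak=streak,
        n_drops=n_drops,
        recovery_left=recovery,
    )


def demonstrator_policy(
    force_history: list[float],
    cfg: DemonstratorConfig,
    joints: np.ndarray | None = None,
) -> np.ndarray:
    """Delayed proportional force correction plus weak posture regulation.

    ``force_history`` holds total pad force per tick, most recent last; the
    demonstrator reacts to the reading ``reaction_delay_ticks`` ago and
    distributes the correction over joints by the fixed synergy vector.
    When the current ``joints`` are given, a posture term pulls them toward
    the synergy-proportional posture with the same closure (a null-space
    motion that leaves the contact forces untouched).
    """
    if len(force_history) < cfg.reaction_delay_ticks + 1:
        raise ValueError("history shorter than the reaction delay")
    observed = force_history[-1 - cfg.reaction_delay_ticks]
    err = cfg.target_force - observed
    dj = cfg.gain * err * SYNERGY
    if joints is not None and cfg.posture_gain > 0:
        joints = np.asarray(joints, dtype=float)
        closure = float(SYNERGY @ joints)
        reference = closure * SYNERGY / float(SYNERGY @ SYNERGY)
        dj = dj + cfg.posture_gain * (reference - joints)
    return np.clip(dj, -MAX_STEP_DEG, MAX_STEP_DEG)


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator,
                         n_channels: int) -> np.ndarray:
    """Unit-variance 20-500 Hz noise carriers, one independent per channel."""
    white = rng.standard_normal((n, n_channels))
    sos = _sig.butter(2, (20.0, 500.0), btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfilt(sos, white, axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    return x / std

# Per-channel sensitivity of the three demonstration electrodes.
_DEMO_CHANNEL_WEIGHTS = np.array([1.0, 0.8, 0.6])


def synthesize_emg(
    effort: np.ndarray,
    cfg: DemonstratorConfig,
    fs: float = EMG_FS_HZ,
    rng: np.random.Generator | None = None,
    tick_rate: float = TICK_RATE,
) -> np.ndarray:
    """Native-rate EMG: band-limited carriers amplitude-modulated by effort.

    ``effort`` is a nonnegative per-tick sequence; the returned array is
    [T_native, 3] mV, clipped to the sensor range.
    """
    effort = np.asarray(effort, dtype=float)
    if np.any(effort < 0):
        raise ValueError("effort must be nonnegative")
    rng = rng or np.random.default_rng(0)
    n_native = int(round(len(effort) * fs / tick_rate))
    carrier = _bandlimited_carrier(n_native, fs, rng, len(_DEMO_CHANNEL_WEIGHTS))
    tick_of_sample = np.minimum(
        (np.arange(n_native) * tick_rate / fs).astype(int), len(effort) - 1
    )
    amp = cfg.emg_gain * effort[tick_of_sample]
    if cfg.emg_noise_sd > 0:
        amp = amp + rng.normal(0.0, cfg.emg_noise_sd, size=amp.shape)
    amp = np.maximum(amp, 0.0)
    x = carrier * amp[:, None] * _DEMO_CHANNEL_WEIGHTS[None, :]
    return np.clip(x, -2.0, 2.0)


def _emg_envelope_per_tick(native: np.ndarray, fs: float, n_ticks: int,
                           tick_rate: float = TICK_RATE) -> np.ndarray:
    """Mean rectified amplitude of native samples per control tick."""
    rect = np.abs(native)
    edges = np.floor(np.arange(n_ticks + 1) * fs / tick_rate).astype(int)
    edges = np.clip(edges, 0, len(rect))
    env = np.zeros((n_ticks, rect.shape[1]))
    for k in range(n_ticks):
        seg = rect[edges[k]:edges[k + 1]]
        if len(seg):
            env[k] = seg.mean(axis=0)
    return env


REST_TICKS = 60          # idle ticks before the task command in a trial
INTENT_EFFORT = 0.25     # EMG effort component signalling active intent
EMG_LEAD_TICKS = 1       # EMG envelope leads motion onset by one tick
GRIP_SHIFT_RATE = 0.3    # per-second rate of null-space grip adjustments
GRIP_SHIFT_SD = 1.0      # degrees per joint of one grip-shift jolt


def compute_effort(total_force: float, dj: np.ndarray, target_force: float,
                   intent: bool = True) -> float:
    """Per-tick muscle effort driving the EMG envelope.

    Effort combines a tonic component present whenever the user is actively
    engaged in the task (intent), the sustained grip level, and phasic
    correction activity.
    """
    base = INTENT_EFFORT if intent else 0.0
    return (base + 0.6 * total_force / target_force
            + 0.4 * float(np.abs(dj).sum()) / MAX_STEP_DEG)


def _null_space_jolt(rng: np.random.Generator) -> np.ndarray:
    """A random posture adjustment that leaves the grip closure unchanged."""
    n = rng.normal(0.0, GRIP_SHIFT_SD, N_JOINTS)
    return n - (SYNERGY @ n) * SYNERGY / float(SYNERGY @ SYNERGY)


def simulate_demonstration(
    task_cfg: TaskConfig,
    demo_cfg: DemonstratorConfig | None = None,
    repetition: int = 1,
    subject_id: str = "S1",
    policy=None,
    rest_ticks: int = REST_TICKS,
) -> MultimodalTrial:
    """Closed loop of plant + demonstrator + EMG synthesis, one trial.

    Each trial starts with a short rest (relaxed EMG, open hand at a
    randomized posture); the task command then raises the tonic EMG level
    and the demonstrator closes, holds the target force, and corrects
    impacts.  Occasional null-space grip shifts exercise the posture-
    restoring behaviour away from the nominal synergy posture.

    Two independent RNG streams (plant, EMG) are derived from the task seed
    so EMG noise never perturbs the dynamics.  ``policy=None`` uses the
    corrective demonstrator; pass a callable ``(force_history) -> dJ`` to
    substitute (e.g. a frozen policy for calibration runs).
    """
    demo_cfg = demo_cfg or DemonstratorConfig()
    ss = np.random.SeedSequence((task_cfg.seed, repetition))
    env_rng, emg_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    state = initial_state()
    state.joints = env_rng.uniform(5.0, 20.0, N_JOINTS)
    forces: list[float] = [state.total_force]
    joints = np.zeros((task_cfg.episode_ticks, N_JOINTS))
    pads = np.zeros((task_cfg.episode_ticks, N_PADS))
    effort = np.zeros(task_cfg.episode_ticks)
    for t in range(task_cfg.episode_ticks):
        active = t >= rest_ticks
        # muscle activation leads motion onset (electromechanical delay), so
        # the EMG channel lets a forecaster time the grasp initiation
        intent = t >= rest_ticks - EMG_LEAD_TICKS
        if not active:
            dj = np.zeros(N_JOINTS)
        elif policy is not None:
            dj = np.asarray(policy(forces), dtype=float)
        elif len(forces) >= demo_cfg.reaction_delay_ticks + 1:
            dj = demonstrator_policy(forces, demo_cfg, joints=state.joints)
            if env_rng.random() < GRIP_SHIFT_RATE / TICK_RATE:
                dj = np.clip(dj + _null_space_jolt(env_rng), -MAX_STEP_DEG, MAX_STEP_DEG)
        else:
            dj = np.zeros(N_JOINTS)
        state = step_environment(state, dj, task_cfg, env_rng)
        joints[t] = state.joints
        pads[t] = state.contact_forces
        effort[t] = compute_effort(state.total_force, dj, demo_cfg.target_force,
                                   intent=intent)
        forces.append(state.total_force)

    native = synthesize_emg(effort, demo_cfg, rng=emg_rng)
    envelope = _emg_envelope_per_tick(native, EMG_FS_HZ, task_cfg.episode_ticks)
    meta = TrialMeta(
        subject_id=subject_id,
        task=task_cfg.task,
        repetition=repetition,
        duration_s=task_cfg.episode_ticks / TICK_RATE,
    )
    return MultimodalTrial(
        tick_rate=TICK_RATE, emg=envelope, tactile=pads, joints=joints, meta=meta
    )


# Per-gesture channel-amplitude signatures (mV); RE is baseline noise only.
GESTURE_SIGNATURES: dict[str, np.ndarray] = {
    "RE": np.array([0.0, 0.0, 0.0]),
    "WE": np.array([0.9, 0.15, 0.1]),
    "WF": np.array([0.1, 0.9, 0.15]),
    "HG": np.array([0.8, 0.8, 0.2]),
    "HO": np.array([0.2, 0.8, 0.8]),
    "WS": np.array([0.8, 0.2, 0.8]),
}


def synthesize_gesture_trial(
    gesture: str,
    duration_s: float = 10.0,
    noise_sd: float = 0.05,
    fs: float = EMG_FS_HZ,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw native-rate EMG [T, 3] for a sustained contraction of one gesture.

    Each gesture modulates the three channels by a fixed amplitude
    signature; a slow (~1.5 Hz) fluctuation and a per-trial amplitude jitter
    emulate natural contraction variability.
    """
    if gesture not in GESTURE_SIGNATURES:
        raise ValueError(f"unknown gesture {gesture!r}; expected one of {GESTURES}")
    rng = rng or np.random.default_rng(0)
    n = int(round(duration_s * fs))
    carrier = _bandlimited_carrier(n, fs, rng, 3)
    t = np.arange(n) / fs
    wobble = 1.0 + 0.15 * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi))
    jitter = rng.uniform(0.85, 1.15)
    amp = GESTURE_SIGNATURES[gesture][None, :] * (jitter * wobble)[:, None]
    noise = noise_sd * _bandlimited_carrier(n, fs, rng, 3)
    return np.clip(carrier * amp + noise, -2.0, 2.0)
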