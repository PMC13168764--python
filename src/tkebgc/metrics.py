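"""Evaluation metrics for offline prediction and closed-loop tool operation.

Grasp quality is judged against the printed force band: a grasp is
*unsuccessful* when all pads read <= 0.1 N (the tool has left the hand),
*suboptimal* when any single pad exceeds 15 N (excessive local load), and
*ideal* otherwise.  Muscle effort is summarized by the integrated (iEMG)
and average (AvEMG) rectified EMG amplitude.  Temporal similarity between
signal sets uses dynamic time warping with the classic |a_i - b_j| local
cost and unit steps; the similarity score maps distance d to
1 / (1 + d / max(len_a, len_b)) so identical sequences score exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GraspOutcome",
    "DtwResult",
    "MetricError",
    "rmse",
    "dtw",
    "classify_grasp_state",
    "count_drops",
    "iemg",
    "avemg",
    "average_contact_force",
    "completion_time",
]

DROP_FORCE_N = 0.1
OVERLOAD_FORCE_N = 15.0


class MetricError(ValueError):
    pass


@dataclass
class GraspOutcome:
    """Per-episode summary of one closed-loop tool-operation run."""

    n_drops: int
    completion_ticks: int
    completed: bool
    f_avg: float                 # N, over active-contact ticks
    iemg: float                  # mV*s, summed over channels
    avemg: float                 # mV
    force_tracking_error: float  # N, mean |F_total - reference| in hold phase
    grasp_states: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_drops < 0 or self.f_avg < 0 or self.iemg < 0:
            raise MetricError("drop count, average force and iEMG must be nonnegative")


@dataclass(frozen=True)
class DtwResult:
    distance: float
    similarity: float
    path_length: int


def rmse(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-joint root-mean-square error and its mean over joints."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    if pred.shape != ref.shape:
        raise MetricError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    per_joint = np.sqrt(np.mean((pred - ref) ** 2, axis=0))
    return per_joint, float(per_joint.mean())


def dtw(a: np.ndarray, b: np.ndarray) -> DtwResult:
    """Dynamic time warping with local cost |a_i - b_j| and steps (1,0),(0,1),(1,1)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise MetricError("DTW inputs must be non-empty")
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    distance = float(acc[n, m])
    # backtrack for the warping-path length
    i, j, length = n, m, 1
    while (i, j) != (1, 1):
        moves = [(acc[i - 1, j - 1], i - 1, j - 1), (acc[i - 1, j], i - 1, j),
                 (acc[i, j - 1], i, j - 1)]
        moves = [(v, ii, jj) for v, ii, jj in moves if ii >= 1 and jj >= 1]
        _, i, j = min(moves)
        length += 1
    similarity = 1.0 / (1.0 + distance / max(n, m))
    return DtwResult(distance=distance, similarity=similarity, path_length=length)


def classify_grasp_state(forces: np.ndarray) -> str:
    """Label one tick of pad forces as ideal / suboptimal / unsuccessful."""
    forces = np.asarray(forces, dtype=float)
    if np.any(forces < 0):
        raise MetricError("contact forces must be nonnegative")
    if np.all(forces <= DROP_FORCE_N):
        return "unsuccessful"
    if np.any(forces > OVERLOAD_FORCE_N):
        return "suboptimal"
    return "ideal"


def count_drops(force_trace: np.ndarray, debounce_ticks: int = 3) -> int:
    """Drop events: entry into the unsuccessful state sustained >= debounce.

    Consecutive unsuccessful ticks count as one event; the grasp must
    recover (leave the unsuccessful state) before a new event can start.
    """
    trace = np.atleast_2d(np.asarray(force_trace, dtype=float))
    unsuccessful = np.all(trace <= DROP_FORCE_N, axis=1)
    drops = 0
    streak = 0
    dropped = False
    for flag in unsuccessful:
        if flag:
            streak += 1
            if streak >= debounce_ticks and not dropped:
                drops += 1
                dropped = True
        else:
            streak = 0
            dropped = False
    return drops


def iemg(emg: np.ndarray, dt: float) -> float:
    """Time integral of rectified amplitude, summed over channels (mV*s)."""
    return float(np.abs(np.asarray(emg, dtype=float)).sum() * dt)


def avemg(emg: np.ndarray) -> float:
    """Mean rectified amplitude over ticks and channels (mV)."""
    return float(np.abs(np.asarray(emg, dtype=float)).mean())


def average_contact_force(force_trace: np.ndarray) -> float:
    """Mean total pad force over ticks with at least one active contact."""
    trace = np.atleast_2d(np.asarray(force_trace, dtype=float))
    active = np.any(trace > DROP_FORCE_N, axis=1)
    if not np.any(active):
        warnings.warn("no tick with active contact; average force reported as 0")
        return 0.0
    return float(trace[active].sum(axis=1).mean())


def completion_time(episode_log: dict) -> int:
    """Ticks from the task command to task completion (censored at the cap)."""
    if "command_tick" not in episode_log:
        raise MetricError("episode log lacks the command-issued marker")
    start = int(episode_log["command_tick"])
    if episode_log.get("done_tick") is not None:
        return int(episode_log["done_tick"]) - start
    if "episode_ticks" not in episode_log:
        raise MetricError("unfinished episode log lacks the episode_ticks cap")
    return int(episode_log["episode_ticks"]) - start
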