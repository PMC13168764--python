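"""Multimodal trial containers, file I/O, manifests, splitting and windowing.

A *trial* is one continuous recording of three time-aligned streams on a
common control-tick grid: surface EMG envelopes (3 channels, mV), tactile
pad forces (9 pads, N) and joint angles (5 joints, degrees).  Trials are the
unit of train/validation/test splitting so that overlapping sliding windows
never leak across subsets.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

GESTURES = ("RE", "WE", "WF", "HG", "HO", "WS")
TASKS = ("hammer", "saw", "peel", "desk")
VALID_LABELS = set(GESTURES) | set(TASKS)

EMG_RANGE_MV = 2.0       # EMG sensor range is [-2, 2] mV
TACTILE_MAX_N = 20.0     # tactile pad saturates near 20 N
JOINT_MAX_DEG = 90.0     # flexion convention, [0, 90] degrees per joint


class ValidationError(ValueError):
    pass


class FormatError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SensorLayout:
    """Channel counts and labels of the acquisition rig."""

    n_emg: int = 3
    n_tactile: int = 9
    n_joint: int = 5
    emg_labels: tuple[str, ...] = ()
    tactile_labels: tuple[str, ...] = ()
    joint_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if min(self.n_emg, self.n_tactile, self.n_joint) < 1:
            raise ValidationError("all channel counts must be >= 1")
        for name, labels, n in (
            ("emg", self.emg_labels or tuple(f"emg_{i+1}" for i in range(self.n_emg)), self.n_emg),
            ("tactile", self.tactile_labels or tuple(f"tac_{i+1}" for i in range(self.n_tactile)), self.n_tactile),
            ("joint", self.joint_labels or tuple(f"joint_{i+1}" for i in range(self.n_joint)), self.n_joint),
        ):
            if len(labels) != n or len(set(labels)) != n:
                raise ValidationError(f"{name} labels must be {n} unique identifiers")
            object.__setattr__(self, f"{name}_labels", tuple(labels))


@dataclass(frozen=True)
class TrialMeta:
    subject_id: str
    task: str
    repetition: int
    duration_s: float = 0.0
    extras: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.task not in VALID_LABELS:
            raise ValidationError(
                f"task {self.task!r} not in the closed vocabulary {sorted(VALID_LABELS)}"
            )
        if self.repetition < 1:
            raise ValidationError("repetition must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.task, self.repetition, self.extras)


@dataclass
class MultimodalTrial:
    """One time-aligned trial on the control-tick grid.

    All three matrices share the row count T; rows are ticks at
    ``tick_rate`` Hz.  EMG rows are per-tick envelope features (mean
    rectified amplitude over the tick interval), so they inherit the
    sensor's [-2, 2] mV bound.
    """

    tick_rate: float
    emg: np.ndarray
    tactile: np.ndarray
    joints: np.ndarray
    meta: TrialMeta

    def __post_init__(self):
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.tactile = np.atleast_2d(np.asarray(self.tactile, dtype=float))
        self.joints = np.atleast_2d(np.asarray(self.joints, dtype=float))
        T = self.emg.shape[0]
        if T < 1:
            raise ValidationError("trial must contain at least one tick")
        if self.tactile.shape[0] != T or self.joints.shape[0] != T:
            raise ValidationError("emg/tactile/joint streams must share the row count")
        if np.any(self.tactile < -1e-12) or np.any(self.tactile > TACTILE_MAX_N + 1e-9):
            raise ValidationError(
                f"tactile forces must lie in [0, {TACTILE_MAX_N}] N (sensor saturation)"
            )
        if np.any(np.abs(self.emg) > EMG_RANGE_MV + 1e-9):
            raise ValidationError(f"EMG values must lie within [-{EMG_RANGE_MV}, {EMG_RANGE_MV}] mV")

    @property
    def n_ticks(self) -> int:
        return self.emg.shape[0]


@dataclass
class ManifestEntry:
    meta: TrialMeta
    path: str = ""


@dataclass
class DatasetManifest:
    trials: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        keys = [e.meta.key for e in self.trials]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (subject, task, repetition) keys in manifest")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def keys(self) -> list[tuple]:
        return [e.meta.key for e in self.trials]


@dataclass
class WindowedSample:
    """A length-P multimodal history with the next joint increment as target."""

    emg_hist: np.ndarray       # [P, N_E]
    tactile_hist: np.ndarray   # [P, N_F]
    joint_hist: np.ndarray     # [P, N_J]
    target_delta: np.ndarray   # [N_J] = J_{t+1} - J_t
    source_trial: tuple


def build_manifest(
    n_subjects: int,
    conditions: list[str],
    n_repetitions: int,
    extra_axes: dict[str, list[str]] | None = None,
) -> DatasetManifest:
    """Full factorial design: subjects x conditions x extra axes x repetitions.

    Extra factorial axes (e.g. control method) are stored in
    ``TrialMeta.extras`` so the (subject, task, repetition, extras) key stays
    unique per cell.
    """
    if n_subjects < 0 or n_repetitions < 0:
        raise ValidationError("counts must be >= 0")
    if len(set(conditions)) != len(conditions):
        raise ValidationError("condition labels must be unique")
    extra_axes = extra_axes or {}
    for name, values in extra_axes.items():
        if len(set(values)) != len(values):
            raise ValidationError(f"values of extra axis {name!r} must be unique")
    axis_names = list(extra_axes)
    axis_values = [extra_axes[name] for name in axis_names]
    entries = []
    for s in range(n_subjects):
        for cond in conditions:
            for combo in product(*axis_values):
                extras = tuple(zip(axis_names, combo))
                for rep in range(1, n_repetitions + 1):
                    entries.append(
                        ManifestEntry(
                            meta=TrialMeta(
                                subject_id=f"S{s + 1}",
                                task=cond,
                                repetition=rep,
                                extras=extras,
                            )
                        )
                    )
    return DatasetManifest(trials=entries)


def align_streams(
    raw_streams: dict[str, tuple[np.ndarray, np.ndarray]],
    tick_rate: float,
    meta: TrialMeta | None = None,
) -> MultimodalTrial:
    """Resample native-rate streams onto a common control-tick grid.

    ``raw_streams`` maps ``"emg" | "tactile" | "joints"`` to (timestamps [s],
    values [n, channels]).  Tactile and joint streams are linearly
    interpolated at tick times; EMG — natively ~2 kHz — is reduced to one
    envelope row per tick: the mean rectified amplitude of the native
    samples falling in that tick interval.
    """
    for name in ("emg", "tactile", "joints"):
        if name not in raw_streams:
            raise ValidationError(f"missing stream {name!r}")
        ts, _ = raw_streams[name]
        ts = np.asarray(ts, dtype=float)
        if ts.size < 2:
            raise ValidationError(f"stream {name!r} needs at least 2 samples")
        if np.any(np.diff(ts) <= 0):
            raise ValidationError(f"stream {name!r} has non-monotone timestamps")
    t0 = max(np.asarray(raw_streams[n][0])[0] for n in ("emg", "tactile", "joints"))
    t1 = min(np.asarray(raw_streams[n][0])[-1] for n in ("emg", "tactile", "joints"))
    if t1 <= t0:
        raise AlignmentError("streams do not overlap in time")
    n_ticks = int(np.floor((t1 - t0) * tick_rate))
    if n_ticks < 1:
        raise AlignmentError("temporal overlap shorter than one tick")
    tick_starts = t0 + np.arange(n_ticks) / tick_rate

    def interp(name: str) -> np.ndarray:
        ts, vals = raw_streams[name]
        vals = np.atleast_2d(np.asarray(vals, dtype=float))
        if vals.shape[0] != len(ts):
            vals = vals.T
        return np.column_stack(
            [np.interp(tick_starts, np.asarray(ts, float), vals[:, c]) for c in range(vals.shape[1])]
        )

    ts_e, emg_vals = raw_streams["emg"]
    ts_e = np.asarray(ts_e, dtype=float)
    emg_vals = np.atleast_2d(np.asarray(emg_vals, dtype=float))
    if emg_vals.shape[0] != len(ts_e):
        emg_vals = emg_vals.T
    rect = np.abs(emg_vals)
    # bin native samples into tick intervals [start, start + 1/rate)
    edges = np.append(tick_starts, tick_starts[-1] + 1.0 / tick_rate)
    idx = np.digitize(ts_e, edges) - 1
    envelope = np.zeros((n_ticks, rect.shape[1]))
    for k in range(n_ticks):
        in_bin = idx == k
        if np.any(in_bin):
            envelope[k] = rect[in_bin].mean(axis=0)
        else:  # sparse stream: fall back to interpolated rectified value
            centre = tick_starts[k] + 0.5 / tick_rate
            envelope[k] = [
                np.interp(centre, ts_e, rect[:, c]) for c in range(rect.shape[1])
            ]

    meta = meta or TrialMeta("S1", "desk", 1, duration_s=n_ticks / tick_rate)
    return MultimodalTrial(
        tick_rate=tick_rate,
        emg=envelope,
        tactile=interp("tactile"),
        joints=interp("joints"),
        meta=meta,
    )


def split_trials(
    manifest: DatasetManifest,
    ratio: tuple[float, float, float] = (6, 2, 2),
    seed: int = 0,
) -> tuple[set, set, set]:
    """Random trial-level partition by largest-remainder apportionment."""
    if len(manifest) == 0:
        raise SplitError("manifest is empty")
    if any(r < 0 for r in ratio) or sum(ratio) <= 0:
        raise SplitError("ratio entries must be nonnegative with positive sum")
    n = len(manifest)
    n_nonzero = sum(1 for r in ratio if r > 0)
    if n < n_nonzero:
        raise SplitError(f"{n} trials cannot fill {n_nonzero} nonempty partitions")
    quotas = np.array(ratio, dtype=float) / sum(ratio) * n
    sizes = np.floor(quotas).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(quotas - sizes), kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    keys = manifest.keys
    bounds = np.cumsum(sizes)
    train = {keys[i] for i in perm[: bounds[0]]}
    val = {keys[i] for i in perm[bounds[0] : bounds[1]]}
    test = {keys[i] for i in perm[bounds[1] :]}
    return train, val, test


def make_windows(trial: MultimodalTrial, P: int) -> list[WindowedSample]:
    """Stride-1 histories of length P with the next-step joint increment.

    Window k covers ticks [k, k+P); its target is J[k+P] - J[k+P-1], the
    increment into the tick after the window.  Short trials (T <= P) give an
    empty list with a warning rather than an error.
    """
    T = trial.n_ticks
    if T <= P:
        warnings.warn(f"trial of {T} ticks is too short for P={P}; no windows emitted")
        return []
    key = trial.meta.key
    return [
        WindowedSample(
            emg_hist=trial.emg[k : k + P],
            tactile_hist=trial.tactile[k : k + P],
            joint_hist=trial.joints[k : k + P],
            target_delta=trial.joints[k + P] - trial.joints[k + P - 1],
            source_trial=key,
        )
        for k in range(T - P)
    ]


# -- file I/O --------------------------------------------------------------

def _trial_header(layout: SensorLayout) -> list[str]:
    return (
        ["time_s"]
        + list(layout.emg_labels)
        + list(layout.tactile_labels)
        + list(layout.joint_labels)
    )


def write_trial(trial: MultimodalTrial, path: str | Path) -> Path:
    """Write one trial as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    layout = SensorLayout(
        n_emg=trial.emg.shape[1],
        n_tactile=trial.tactile.shape[1],
        n_joint=trial.joints.shape[1],
    )
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(_trial_header(layout))
    times = np.arange(trial.n_ticks) / trial.tick_rate
    for k in range(trial.n_ticks):
        writer.writerow(
            [f"{times[k]:.12g}"]
            + [f"{v:.17g}" for v in trial.emg[k]]
            + [f"{v:.17g}" for v in trial.tactile[k]]
            + [f"{v:.17g}" for v in trial.joints[k]]
        )
    path.write_text(buf.getvalue())
    sidecar = {
        "tick_rate": trial.tick_rate,
        "subject_id": trial.meta.subject_id,
        "task": trial.meta.task,
        "repetition": trial.meta.repetition,
        "duration_s": trial.meta.duration_s,
        "extras": dict(trial.meta.extras),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trial(path: str | Path, layout: SensorLayout | None = None) -> MultimodalTrial:
    path = Path(path)
    layout = layout or SensorLayout()
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path.name}")
    side = json.loads(sidecar_path.read_text())
    expected = _trial_header(layout)
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError("empty trial file")
        missing = [c for c in expected if c not in header]
        if missing:
            raise FormatError(f"missing columns: {', '.join(missing)}")
        col = {name: header.index(name) for name in expected}
        rows = list(reader)
    if not rows:
        raise FormatError("trial file has no data rows")

    def parse(row_i: int, row: list[str], name: str) -> float:
        try:
            return float(row[col[name]])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"non-numeric cell at row {row_i}, column {name}") from exc

    emg = np.empty((len(rows), layout.n_emg))
    tactile = np.empty((len(rows), layout.n_tactile))
    joints = np.empty((len(rows), layout.n_joint))
    for i, row in enumerate(rows):
        for j, name in enumerate(layout.emg_labels):
            v = parse(i, row, name)
            if abs(v) > EMG_RANGE_MV + 1e-9:
                raise FormatError(
                    f"row {i}, column {name}: EMG {v} mV outside the [-2, 2] mV sensor range"
                )
            emg[i, j] = v
        for j, name in enumerate(layout.tactile_labels):
            v = parse(i, row, name)
            if v < -1e-9 or v > TACTILE_MAX_N + 1e-9:
                raise FormatError(
                    f"row {i}, column {name}: force {v} N outside [0, {TACTILE_MAX_N}] N "
                    "(pad saturates near 20 N)"
                )
            tactile[i, j] = v
        for j, name in enumerate(layout.joint_labels):
            joints[i, j] = parse(i, row, name)
    meta = TrialMeta(
        subject_id=side.get("subject_id", "S1"),
        task=side.get("task", "desk"),
        repetition=int(side.get("repetition", 1)),
        duration_s=float(side.get("duration_s", len(rows) / side["tick_rate"])),
        extras=tuple(sorted(side.get("extras", {}).items())),
    )
    return MultimodalTrial(
        tick_rate=float(side["tick_rate"]), emg=emg, tactile=tactile, joints=joints, meta=meta
    )


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    records = [
        {
            "subject_id": e.meta.subject_id,
            "task": e.meta.task,
            "repetition": e.meta.repetition,
            "duration_s": e.meta.duration_s,
            "extras": dict(e.meta.extras),
            "path": e.path,
        }
        for e in manifest.trials
    ]
    path.write_text(json.dumps(records, indent=1))
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    records = json.loads(Path(path).read_text())
    return DatasetManifest(
        trials=[
            ManifestEntry(
                meta=TrialMeta(
                    subject_id=r["subject_id"],
                    task=r["task"],
                    repetition=int(r["repetition"]),
                    duration_s=float(r.get("duration_s", 0.0)),
                    extras=tuple(sorted(r.get("extras", {}).items())),
                ),
                path=r.get("path", ""),
            )
            for r in records
        ]
    )
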