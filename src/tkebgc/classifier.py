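"""Gesture-intent recognition on preprocessed EMG windows.

A compact convolutional + recurrent network (two 1-D conv layers feeding a
single GRU) maps 256 ms rectified-EMG windows to the six gestures — rest
(RE), wrist extension (WE), wrist flexion (WF), hand grasp (HG), hand open
(HO) and wrist supination (WS) — which trigger predefined grasp commands.

Splitting happens at trial level and is *enforced*: training aborts if any
trial contributes windows to more than one subset, since overlapping
windows from one trial would otherwise leak between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import GESTURES
from .preproc import (
    FilterSpec,
    WindowSpec,
    preprocess_emg,
    DEFAULT_BANDPASS,
    DEFAULT_NOTCH,
    DEFAULT_WINDOW,
)

__all__ = [
    "GestureDataset",
    "ClassifierConfig",
    "GestureClassifier",
    "LeakError",
    "build_gesture_dataset",
    "train_classifier",
    "predict_gesture",
    "gesture_to_command",
    "confusion_matrix",
]

LABEL_TO_INDEX = {g: i for i, g in enumerate(GESTURES)}

GESTURE_COMMANDS = {
    "HG": "grasp",
    "HO": "release",
    "RE": "hold",
    "WE": "wrist_extend",
    "WF": "wrist_flex",
    "WS": "wrist_supinate",
}


class LeakError(RuntimeError):
    pass


@dataclass
class GestureDataset:
    windows: np.ndarray            # [M, W, N_E] preprocessed (rectified) EMG
    labels: np.ndarray             # [M] integer gesture indices
    trial_keys: list               # [M] source trial per window

    def __post_init__(self):
        if not (len(self.windows) == len(self.labels) == len(self.trial_keys)):
            raise ValueError("windows, labels and trial keys must align")
        if len(self.labels) and not set(np.unique(self.labels)) <= set(range(len(GESTURES))):
            raise ValueError("labels must index the 6-gesture vocabulary")

    def subset(self, keys: set) -> "GestureDataset":
        mask = np.array([k in keys for k in self.trial_keys])
        return GestureDataset(
            self.windows[mask],
            self.labels[mask],
            [k for k, m in zip(self.trial_keys, mask) if m],
        )


@dataclass
class ClassifierConfig:
    conv_channels: tuple[int, int] = (16, 32)
    kernel: int = 5
    subsample: int = 4            # temporal stride between conv stages
    gru_hidden: int = 64
    classes: int = 6
    lr: float = 2e-3
    batch: int = 64
    epochs: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.classes != 6:
            raise ValueError("the gesture vocabulary has exactly 6 classes")


def build_gesture_dataset(
    trials: list[tuple[np.ndarray, str, object]],
    fs_hz: float = 2000.0,
    decimate: int = 4,
    bandpass_spec: FilterSpec | None = None,
    notch_spec: FilterSpec | None = None,
    window_spec: WindowSpec | None = None,
) -> GestureDataset:
    """Preprocess raw native-rate trials into labeled classifier windows.

    Each trial is (raw EMG [T, N_E], gesture label, trial key).  The full
    conditioning chain (band-pass, notch, rectify, segment) runs per trial;
    windows are then envelope-decimated by block averaging to keep the
    recurrent unrolling short.
    """
    bandpass_spec = bandpass_spec or DEFAULT_BANDPASS(fs_hz)
    notch_spec = notch_spec or DEFAULT_NOTCH(fs_hz)
    window_spec = window_spec or DEFAULT_WINDOW(fs_hz)
    all_windows, labels, keys = [], [], []
    for raw, gesture, key in trials:
        if gesture not in LABEL_TO_INDEX:
            raise ValueError(f"unknown gesture label {gesture!r}")
        for win in preprocess_emg(raw, bandpass_spec, notch_spec, window_spec):
            if decimate > 1:
                usable = (len(win) // decimate) * decimate
                win = win[:usable].reshape(-1, decimate, win.shape[1]).mean(axis=1)
            all_windows.append(win)
            labels.append(LABEL_TO_INDEX[gesture])
            keys.append(key)
    if not all_windows:
        return GestureDataset(np.zeros((0, 0, 0)), np.zeros(0, dtype=int), [])
    return GestureDataset(np.stack(all_windows), np.asarray(labels, dtype=int), keys)


class GestureClassifier(nn.Module):
    def __init__(self, config: ClassifierConfig, n_channels: int = 3,
                 rng: np.random.Generator | None = None):
        cfg = config
        self.config = cfg
        rng = rng or np.random.default_rng(cfg.seed)
        c1, c2 = cfg.conv_channels
        self.conv1 = nn.Conv1d(n_channels, c1, cfg.kernel, rng)
        self.conv2 = nn.Conv1d(c1, c2, cfg.kernel, rng)
        self.gru = nn.GRU(c2, cfg.gru_hidden, rng)
        self.head = nn.Linear(cfg.gru_hidden, cfg.classes, rng)
        self.norm_scale = 1.0

    def logits(self, windows: np.ndarray) -> nn.Tensor:
        x = nn.Tensor(np.asarray(windows, dtype=float) / self.norm_scale)
        s = self.config.subsample
        x = self.conv1(x).relu()[(slice(None), slice(None, None, s))]
        x = self.conv2(x).relu()[(slice(None), slice(None, None, s))]
        return self.head(self.gru(x))

    def predict(self, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, class scores); scores are softmax rows summing to 1."""
        windows = np.asarray(windows, dtype=float)
        squeeze = windows.ndim == 2
        if squeeze:
            windows = windows[None]
        scores = nn.softmax(self.logits(windows), axis=-1).data
        labels = scores.argmax(axis=-1)  # argmax breaks ties by index order
        if squeeze:
            return labels[0], scores[0]
        return labels, scores


def _assert_leak_free(*key_sets: set) -> None:
    for i in range(len(key_sets)):
        for j in range(i + 1, len(key_sets)):
            overlap = key_sets[i] & key_sets[j]
            if overlap:
                raise LeakError(
                    f"trial(s) {sorted(map(str, overlap))[:3]} appear in more than one "
                    "subset; windows from one trial must stay in a single subset"
                )


def train_classifier(
    dataset: GestureDataset,
    train_keys: set,
    val_keys: set,
    config: ClassifierConfig,
    verbose: bool = False,
) -> tuple[GestureClassifier, dict]:
    """Cross-entropy training with an enforced leak-free trial split."""
    _assert_leak_free(set(train_keys), set(val_keys))
    train_set = dataset.subset(set(train_keys))
    val_set = dataset.subset(set(val_keys))
    if len(train_set.windows) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)
    clf = GestureClassifier(config, n_channels=train_set.windows.shape[-1], rng=rng)
    clf.norm_scale = max(float(np.abs(train_set.windows).mean()), 1e-6)
    params = clf.parameters()
    opt = nn.Adam(params, lr=config.lr)
    X, y = train_set.windows, train_set.labels
    history = {"train_loss": [], "val_acc": []}
    best_acc, best_state = -1.0, None
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        total = 0.0
        for start in range(0, len(X), config.batch):
            idx = order[start : start + config.batch]
            opt.zero_grad()
            loss = nn.cross_entropy(clf.logits(X[idx]), y[idx])
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        history["train_loss"].append(total / len(X))
        if len(val_set.windows):
            pred, _ = clf.predict(val_set.windows)
            acc = float(np.mean(pred == val_set.labels))
            history["val_acc"].append(acc)
            if acc > best_acc:
                best_acc = acc
                best_state = [p.data.copy() for p in params]
        if verbose:
            print(f"epoch {epoch + 1}: loss {history['train_loss'][-1]:.4f}"
                  + (f" val acc {history['val_acc'][-1]:.3f}" if history["val_acc"] else ""))
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data = saved
    return clf, history


def predict_gesture(clf: GestureClassifier, window: np.ndarray) -> tuple[str, np.ndarray]:
    label_idx, scores = clf.predict(window)
    return GESTURES[int(label_idx)], scores


def gesture_to_command(label: str) -> str:
    if label not in GESTURE_COMMANDS:
        raise ValueError(f"unknown gesture label {label!r}")
    return GESTURE_COMMANDS[label]


def confusion_matrix(predictions: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """6x6 count matrix (rows = true class) and per-class accuracy."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    k = len(GESTURES)
    mat = np.zeros((k, k), dtype=int)
    np.add.at(mat, (labels, predictions), 1)
    row_sums = mat.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row_sums > 0, np.diag(mat) / np.maximum(row_sums, 1), np.nan)
    return mat, per_class
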