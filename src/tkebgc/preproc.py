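"""sEMG conditioning: band-pass, power-line notch, rectification, windowing.

The chain mirrors standard myoelectric practice: a 2nd-order Butterworth
band-pass (20–500 Hz) removes baseline drift and high-frequency noise, a
50 Hz notch removes mains interference, full-wave rectification exposes the
amplitude envelope, and fixed 256 ms windows with a 128 ms step feed the
gesture classifier.

Filters run causally (zero initial state) by default — the mode an online
controller needs — with an optional zero-phase forward–backward mode for
offline analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "SpecError",
    "bandpass",
    "notch",
    "rectify",
    "segment_windows",
    "preprocess_emg",
    "DEFAULT_BANDPASS",
    "DEFAULT_NOTCH",
    "DEFAULT_WINDOW",
]


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    kind: str                      # "bandpass" | "notch"
    fs_hz: float
    order: int = 2
    band_hz: tuple[float, float] | float = (20.0, 500.0)
    q_factor: float = 30.0

    def __post_init__(self):
        nyq = self.fs_hz / 2.0
        if self.order < 1:
            raise SpecError("filter order must be >= 1")
        if self.kind == "bandpass":
            low, high = self.band_hz  # type: ignore[misc]
            if not (0 < low < high < nyq):
                raise SpecError(
                    f"bandpass edges must satisfy 0 < {low} < {high} < Nyquist ({nyq} Hz)"
                )
        elif self.kind == "notch":
            centre = float(self.band_hz) if np.isscalar(self.band_hz) else self.band_hz[0]
            if not (0 < centre < nyq):
                raise SpecError(f"notch centre {centre} Hz outside (0, Nyquist)")
            if self.q_factor <= 0:
                raise SpecError("notch Q must be positive")
        else:
            raise SpecError(f"unknown filter kind {self.kind!r}")

    def sos(self) -> np.ndarray:
        if self.kind == "bandpass":
            return signal.butter(
                self.order, self.band_hz, btype="bandpass", fs=self.fs_hz, output="sos"
            )
        centre = float(self.band_hz) if np.isscalar(self.band_hz) else self.band_hz[0]
        b, a = signal.iirnotch(centre, self.q_factor, fs=self.fs_hz)
        return signal.tf2sos(b, a)

    def gain_at(self, freq_hz: float) -> float:
        """Magnitude of the designed response at ``freq_hz`` (oracle for tests)."""
        _, h = signal.sosfreqz(self.sos(), worN=[freq_hz], fs=self.fs_hz)
        return float(np.abs(h[0]))


@dataclass(frozen=True)
class WindowSpec:
    fs_hz: float
    window_ms: float = 256.0
    step_ms: float = 128.0

    def __post_init__(self):
        if not (self.window_ms >= self.step_ms > 0):
            raise SpecError("require window_ms >= step_ms > 0")
        if self.window_samples < 1:
            raise SpecError("window shorter than one sample")

    @property
    def window_samples(self) -> int:
        return round(self.window_ms * self.fs_hz / 1000.0)

    @property
    def step_samples(self) -> int:
        return round(self.step_ms * self.fs_hz / 1000.0)


def _apply(spec: FilterSpec, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3 * spec.order:
        raise SpecError(f"signal of length {x.shape[0]} too short for order {spec.order}")
    sos = spec.sos()
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def bandpass(x: np.ndarray, spec: FilterSpec, zero_phase: bool = False) -> np.ndarray:
    if spec.kind != "bandpass":
        raise SpecError("spec.kind must be 'bandpass'")
    return _apply(spec, x, zero_phase)


def notch(x: np.ndarray, spec: FilterSpec, zero_phase: bool = False) -> np.ndarray:
    if spec.kind != "notch":
        raise SpecError("spec.kind must be 'notch'")
    return _apply(spec, x, zero_phase)


def rectify(x: np.ndarray) -> np.ndarray:
    return np.abs(np.asarray(x, dtype=float))


def segment_windows(x: np.ndarray, spec: WindowSpec) -> list[np.ndarray]:
    """Slice [T, C] into windows of W samples every S samples.

    Yields floor((T - W)/S) + 1 windows when T >= W, else an empty list.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T = x.shape[0]
    W, S = spec.window_samples, spec.step_samples
    if T < W:
        return []
    count = (T - W) // S + 1
    return [x[i * S : i * S + W] for i in range(count)]


def preprocess_emg(
    x: np.ndarray,
    bandpass_spec: FilterSpec,
    notch_spec: FilterSpec,
    window_spec: WindowSpec,
    zero_phase: bool = False,
) -> list[np.ndarray]:
    """Band-pass -> notch -> full-wave rectification -> segmentation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return []
    return segment_windows(
        rectify(notch(bandpass(x, bandpass_spec, zero_phase), notch_spec, zero_phase)),
        window_spec,
    )


def DEFAULT_BANDPASS(fs_hz: float = 2000.0) -> FilterSpec:
    return FilterSpec(kind="bandpass", fs_hz=fs_hz, order=2, band_hz=(20.0, 500.0))


def DEFAULT_NOTCH(fs_hz: float = 2000.0) -> FilterSpec:
    return FilterSpec(kind="notch", fs_hz=fs_hz, band_hz=50.0, q_factor=30.0)


def DEFAULT_WINDOW(fs_hz: float = 2000.0) -> WindowSpec:
    return WindowSpec(fs_hz=fs_hz, window_ms=256.0, step_ms=128.0)
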