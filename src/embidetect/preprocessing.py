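"""Signal conditioning ahead of detection.

Three fixed roles:

* high-pass the raw EMG to remove DC offset and motion drift,
* rectify + low-pass the filtered EMG into a nonnegative amplitude envelope
  (the input of the double-threshold burst detector),
* low-pass the bioimpedance channel so that valley morphology (a sub-5 Hz
  phenomenon) survives while measurement noise is suppressed.

All filters are Butterworth, applied forward-backward by default so that no
landmark time shift is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .io import EMBIRecording, ValidationError

__all__ = ["FilterSpec", "apply_filter", "highpass_emg", "emg_envelope", "smooth_bi"]


@dataclass(frozen=True)
class FilterSpec:
    """A one-sided Butterworth filter: kind is ``highpass`` or ``lowpass``."""

    kind: str
    cutoff_hz: float
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if self.cutoff_hz <= 0:
            raise ValidationError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValidationError("order must be >= 1")


def apply_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply *spec* to *x*; length-preserving, linear, deterministic."""
    if spec.cutoff_hz >= fs / 2:
        raise ValidationError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist ({fs / 2} Hz at fs={fs} Hz)"
        )
    sos = butter(spec.order, spec.cutoff_hz, btype=spec.kind, fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    return sosfiltfilt(sos, x) if spec.zero_phase else sosfilt(sos, x)


def highpass_emg(
    rec: EMBIRecording, spec: FilterSpec | None = None
) -> np.ndarray:
    """High-pass filter the EMG channel of *rec* (default 20 Hz, order 4)."""
    if spec is None:
        spec = FilterSpec("highpass", 20.0, order=4)
    return apply_filter(rec.emg, rec.fs, spec)


def emg_envelope(
    emg_filtered: np.ndarray,
    fs: float,
    lowpass_hz: float = 10.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Full-wave rectification followed by low-pass smoothing.

    The result is nonnegative and positively homogeneous: scaling the input by
    ``c > 0`` scales the envelope by ``c``.
    """
    spec = FilterSpec("lowpass", lowpass_hz, order=order, zero_phase=zero_phase)
    env = apply_filter(np.abs(np.asarray(emg_filtered, dtype=float)), fs, spec)
    # the low-pass step can undershoot slightly below zero near sharp edges
    return np.maximum(env, 0.0)


def smooth_bi(
    bi: np.ndarray,
    fs: float,
    lowpass_hz: float = 5.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass the bioimpedance channel, preserving slow valley morphology."""
    spec = FilterSpec("lowpass", lowpass_hz, order=order, zero_phase=zero_phase)
    return apply_filter(bi, fs, spec)
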