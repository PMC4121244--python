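"""Double-threshold detection of submental EMG activity.

Swallowing is impossible without muscle activity, so an EMG burst is the first
selection criterion of the two-stage detector. Burst boundaries are found on
the rectified-and-smoothed envelope with amplitude hysteresis plus dwell-time
criteria:

* a segment *opens* where the envelope stays at or above
  ``mu + k_on * sigma`` for at least ``min_above_s``,
* it *closes* where the envelope stays below ``mu + k_off * sigma``
  (``k_off < k_on``) for at least ``min_below_s``,
* segments closer than ``max_gap_merge_s`` are merged, then segments shorter
  than ``min_duration_s`` are discarded.

``mu`` and ``sigma`` are pooled over the lowest-activity windows of the
recording, so recordings that start mid-activity are handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError

__all__ = [
    "DoubleThresholdParams",
    "EMGActivitySegment",
    "estimate_baseline",
    "detect_emg_activity",
]

#: Absolute floor on the baseline spread (mV). With a perfectly constant
#: envelope the onset threshold sits just above the constant, so nothing is
#: ever "active" relative to a featureless baseline.
SIGMA_FLOOR_MV = 1e-9


@dataclass(frozen=True)
class DoubleThresholdParams:
    """Hysteresis and dwell-time parameters of the burst detector."""

    baseline_window_s: float = 1.0
    k_on: float = 4.0
    k_off: float = 1.5
    min_above_s: float = 0.05
    min_below_s: float = 0.2
    min_duration_s: float = 0.2
    max_gap_merge_s: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "baseline_window_s",
            "min_above_s",
            "min_below_s",
            "min_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_gap_merge_s < 0:
            raise ValidationError("max_gap_merge_s must be >= 0")
        if not self.k_off < self.k_on:
            raise ValidationError("k_off must be smaller than k_on")


@dataclass(frozen=True)
class EMGActivitySegment:
    """A detected burst with its landmark times (seconds) and amplitudes."""

    t_start: float
    t_max: float
    t_end: float
    peak_mv: float
    rms_mv: float


def estimate_baseline(
    envelope: np.ndarray, fs: float, params: DoubleThresholdParams
) -> tuple[float, float]:
    """Noise statistics ``(mu, sigma)`` from the lowest-activity windows.

    Windows of length ``baseline_window_s`` are ranked by mean envelope, and
    the statistics are pooled over every window whose mean lies within the
    robust window-to-window spread of the minimum. Pooling matters: the
    single quietest window is atypically quiet by selection, which biases
    both ``mu`` and ``sigma`` low and places the hysteresis thresholds inside
    the noise band.
    """
    envelope = np.asarray(envelope, dtype=float)
    w = int(round(params.baseline_window_s * fs))
    w = max(w, 2)
    n = len(envelope)
    if n < w:
        raise ValidationError(
            f"recording ({n} samples) shorter than baseline window ({w})"
        )
    stride = max(1, w // 4)
    c = np.concatenate(([0.0], np.cumsum(envelope)))
    starts = np.arange(0, n - w + 1, stride)
    means = (c[starts + w] - c[starts]) / w
    mad = float(np.median(np.abs(means - np.median(means))))
    cut = means.min() + 1.4826 * mad
    mask = np.zeros(n, dtype=bool)
    for s in starts[means <= cut]:
        mask[s : s + w] = True
    quiet = envelope[mask]
    return float(quiet.mean()), float(quiet.std())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``[start, stop)`` runs of True in *mask*."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_emg_activity(
    envelope: np.ndarray,
    fs: float,
    params: DoubleThresholdParams | None = None,
    t0: float = 0.0,
) -> list[EMGActivitySegment]:
    """Detect EMG bursts on the envelope; output sorted and non-overlapping.

    Returns an empty list when the envelope carries no distinguishable
    activity (including the degenerate all-constant case).
    """
    if params is None:
        params = DoubleThresholdParams()
    envelope = np.asarray(envelope, dtype=float)
    mu, sigma = estimate_baseline(envelope, fs, params)
    sigma = max(sigma, SIGMA_FLOOR_MV)
    thr_on = mu + params.k_on * sigma
    thr_off = mu + params.k_off * sigma

    n_above = max(1, int(np.ceil(params.min_above_s * fs)))
    n_below = max(1, int(np.ceil(params.min_below_s * fs)))

    onset_runs = [r for r in _runs(envelope >= thr_on) if r[1] - r[0] >= n_above]
    close_runs = [r for r in _runs(envelope < thr_off) if r[1] - r[0] >= n_below]

    # raw segments: open at a qualifying onset run, close at the start of the
    # next qualifying below-threshold run (or the end of the recording)
    raw: list[tuple[int, int]] = []
    ci = 0
    pos = 0
    for o_start, _o_stop in onset_runs:
        if o_start < pos:
            continue
        while ci < len(close_runs) and close_runs[ci][0] < o_start:
            ci += 1
        if ci < len(close_runs):
            end, pos = close_runs[ci][0], close_runs[ci][1]
        else:
            end = pos = len(envelope)
        raw.append((o_start, end))

    # merge across short gaps, then enforce the minimum duration
    merged: list[list[int]] = []
    for s, e in raw:
        if merged and (s - merged[-1][1]) / fs < params.max_gap_merge_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    n_min = int(np.ceil(params.min_duration_s * fs))
    kept = [(s, e) for s, e in merged if e - s >= n_min]

    segments = []
    for s, e in kept:
        chunk = envelope[s:e]
        imax = s + int(np.argmax(chunk))  # earliest maximum on ties
        segments.append(
            EMGActivitySegment(
                t_start=t0 + s / fs,
                t_max=t0 + imax / fs,
                t_end=t0 + e / fs,
                peak_mv=float(chunk.max()),
                rms_mv=float(np.sqrt(np.mean(chunk**2))),
            )
        )
    return segments
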