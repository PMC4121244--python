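"""Reading and writing of recordings, event annotations and pipeline configuration.

The interchange formats are deliberately plain: comma-separated text with a
header row and ``.`` as the decimal mark.

* Recording CSV: columns ``time_s, emg_mV, bi_ohm``, one row per sample, a
  single common sampling rate for both channels.
* Annotation CSV: columns ``label, sublabel, onset_s, offset_s``; intervals are
  half-open ``[onset, offset)`` in seconds from the start of the recording.
* Configuration: a flat key-value YAML mapping onto :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EMBIError",
    "LoadError",
    "MissingColumnError",
    "NonUniformTimebaseError",
    "NonFiniteDataError",
    "ValidationError",
    "EMBIRecording",
    "EventAnnotation",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
]

COHORT_TAGS = ("healthy", "patient", "unknown")
EVENT_LABELS = ("swallow", "nonswallow")

#: Relative jitter of the sample clock above which a time base is rejected.
MAX_RELATIVE_JITTER = 1e-6


class EMBIError(Exception):
    """Base class for all errors raised by this package."""


class LoadError(EMBIError):
    """A file could not be interpreted as the requested object."""


class MissingColumnError(LoadError):
    """A required column is absent from a delimited-text file."""


class NonUniformTimebaseError(LoadError):
    """The time column is not an arithmetic progression within tolerance."""


class NonFiniteDataError(LoadError):
    """NaN or infinite samples were found after loading."""


class ValidationError(EMBIError, ValueError):
    """An in-memory object violates a documented invariant."""


@dataclass
class EMBIRecording:
    """A synchronized two-channel recording: submental EMG and cervical bioimpedance.

    Parameters
    ----------
    subject_id : str
        Opaque identifier of the subject / recording session.
    fs : float
        Common sampling rate of both channels, Hz.
    t : ndarray
        Sample times in seconds, ``t[i] = t[0] + i / fs``.
    emg : ndarray
        Surface EMG samples, mV.
    bi : ndarray
        Bioimpedance samples, ohm.
    cohort_tag : str
        One of ``healthy``, ``patient``, ``unknown``.
    """

    subject_id: str
    fs: float
    t: np.ndarray
    emg: np.ndarray
    bi: np.ndarray
    cohort_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.bi = np.asarray(self.bi, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.t)
        if n < 2:
            raise ValidationError(f"a recording needs at least 2 samples, got {n}")
        if len(self.emg) != n or len(self.bi) != n:
            raise ValidationError(
                "channel lengths differ: "
                f"t={n}, emg={len(self.emg)}, bi={len(self.bi)}"
            )
        for name, arr in (("t", self.t), ("emg", self.emg), ("bi", self.bi)):
            if not np.all(np.isfinite(arr)):
                raise NonFiniteDataError(f"non-finite values in column '{name}'")
        dt = np.diff(self.t)
        step = 1.0 / self.fs
        if np.max(np.abs(dt - step)) > MAX_RELATIVE_JITTER * step:
            raise NonUniformTimebaseError(
                "time base does not match fs=%g Hz within %g relative jitter"
                % (self.fs, MAX_RELATIVE_JITTER)
            )
        if self.cohort_tag not in COHORT_TAGS:
            raise ValidationError(
                f"cohort_tag must be one of {COHORT_TAGS}, got {self.cohort_tag!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled event interval, half-open ``[onset_s, offset_s)``."""

    label: str
    sublabel: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValidationError(
                f"label must be one of {EVENT_LABELS}, got {self.label!r}"
            )
        if not self.onset_s < self.offset_s:
            raise ValidationError(
                f"onset must precede offset: [{self.onset_s}, {self.offset_s})"
            )

    def contains(self, t: float) -> bool:
        return self.onset_s <= t < self.offset_s


def validate_annotations(events: Sequence[EventAnnotation]) -> list[EventAnnotation]:
    """Sort events by onset and check same-label intervals do not overlap."""
    out = sorted(events, key=lambda e: (e.onset_s, e.offset_s))
    last_end: dict[str, float] = {}
    for ev in out:
        if ev.onset_s < last_end.get(ev.label, -np.inf):
            raise ValidationError(
                f"overlapping {ev.label!r} events at onset {ev.onset_s}"
            )
        last_end[ev.label] = ev.offset_s
    return out


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

RECORDING_COLUMNS = ("time_s", "emg_mV", "bi_ohm")


def read_recording(path, fs_expected: float | None = None) -> EMBIRecording:
    """Load a recording CSV and validate its time base.

    The sampling rate is inferred from the median time step; if *fs_expected*
    is given it must agree within one part per million.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"{path.name}: missing column '{col}'")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValidationError(f"{path.name}: a recording needs at least 2 samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise NonUniformTimebaseError(f"{path.name}: non-increasing time column")
    if np.max(np.abs(dt - step)) > MAX_RELATIVE_JITTER * step:
        raise NonUniformTimebaseError(
            f"{path.name}: time step jitter exceeds {MAX_RELATIVE_JITTER} relative"
        )
    fs = 1.0 / step
    if fs_expected is not None and abs(fs - fs_expected) > MAX_RELATIVE_JITTER * fs_expected:
        raise NonUniformTimebaseError(
            f"{path.name}: inferred fs={fs:g} Hz does not match expected {fs_expected:g} Hz"
        )
    meta = _read_comment_meta(path)
    return EMBIRecording(
        subject_id=meta.get("subject_id", path.stem),
        fs=fs,
        t=t,
        emg=df["emg_mV"].to_numpy(float),
        bi=df["bi_ohm"].to_numpy(float),
        cohort_tag=meta.get("cohort_tag", "unknown"),
    )


def write_recording(rec: EMBIRecording, path) -> None:
    """Write a recording as CSV, lossless to ~1e-12 relative precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id}\n# cohort_tag={rec.cohort_tag}\n")
        pd.DataFrame(
            {"time_s": rec.t, "emg_mV": rec.emg, "bi_ohm": rec.bi}
        ).to_csv(fh, index=False, float_format="%.12g")


def _read_comment_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
                meta[key.strip()] = val.strip()
    return meta


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("label", "sublabel", "onset_s", "offset_s")


def read_annotations(path) -> list[EventAnnotation]:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"{path.name}: missing column '{col}'")
    events = [
        EventAnnotation(
            label=str(row.label),
            sublabel="" if pd.isna(row.sublabel) else str(row.sublabel),
            onset_s=float(row.onset_s),
            offset_s=float(row.offset_s),
        )
        for row in df.itertuples()
    ]
    return validate_annotations(events)


def write_annotations(events: Sequence[EventAnnotation], path) -> None:
    events = validate_annotations(events)
    pd.DataFrame(
        {
            "label": [e.label for e in events],
            "sublabel": [e.sublabel for e in events],
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
        }
    ).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _rng(lo, hi, lo_open=False, hi_open=False):
    """Range descriptor used by PipelineConfig validation."""
    return (lo, hi, lo_open, hi_open)


@dataclass
class PipelineConfig:
    """All tunable parameters of the detection pipeline, with units.

    Defaults are the package defaults used throughout the documentation; every
    value can be overridden from a flat key-value YAML file.
    """

    # -- preprocessing (Hz / filter orders)
    emg_highpass_hz: float = 20.0
    emg_highpass_order: int = 4
    envelope_lowpass_hz: float = 10.0
    envelope_lowpass_order: int = 2
    bi_lowpass_hz: float = 5.0
    bi_lowpass_order: int = 2
    zero_phase: bool = True
    # -- EMG double-threshold detector
    baseline_window_s: float = 1.0
    k_on: float = 4.0
    k_off: float = 1.5
    min_above_s: float = 0.05
    min_below_s: float = 0.2
    min_duration_s: float = 0.2
    max_gap_merge_s: float = 0.2
    # -- bioimpedance PLA + valley conditions
    pla_epsilon_ohm: float = 0.05
    pla_piece_s: float = 0.05
    min_depth_ohm: float = 0.3
    min_total_s: float = 0.2
    max_total_s: float = 3.0
    min_descent_s: float = 0.1
    max_descent_slope_ohm_s: float = -0.5
    flat_slope_ohm_s: float = 0.25
    max_flat_bottom_s: float = 0.5
    # -- candidate pairing and classification
    grace_s: float = 0.5
    svm_c: float = 1.0
    svm_gamma: float | str = "median"
    decision_threshold: float = 0.0

    _RANGES = {
        "emg_highpass_hz": _rng(0, np.inf, lo_open=True),
        "emg_highpass_order": _rng(1, 8),
        "envelope_lowpass_hz": _rng(0, np.inf, lo_open=True),
        "envelope_lowpass_order": _rng(1, 8),
        "bi_lowpass_hz": _rng(0, np.inf, lo_open=True),
        "bi_lowpass_order": _rng(1, 8),
        "baseline_window_s": _rng(0, 60, lo_open=True),
        "k_on": _rng(0, np.inf, lo_open=True),
        "k_off": _rng(0, np.inf, lo_open=True),
        "min_above_s": _rng(0, 10, lo_open=True),
        "min_below_s": _rng(0, 10, lo_open=True),
        "min_duration_s": _rng(0, 10, lo_open=True),
        "max_gap_merge_s": _rng(0, 10),
        "pla_epsilon_ohm": _rng(0, np.inf, lo_open=True),
        "pla_piece_s": _rng(0, 1, lo_open=True),
        "min_depth_ohm": _rng(0, np.inf, lo_open=True),
        "min_total_s": _rng(0, np.inf, lo_open=True),
        "max_total_s": _rng(0, np.inf, lo_open=True),
        "min_descent_s": _rng(0, np.inf, lo_open=True),
        "max_descent_slope_ohm_s": _rng(-np.inf, 0, hi_open=True),
        "flat_slope_ohm_s": _rng(0, np.inf),
        "max_flat_bottom_s": _rng(0, np.inf),
        "grace_s": _rng(0, np.inf),
        "svm_c": _rng(0, np.inf, lo_open=True),
        "decision_threshold": _rng(-np.inf, np.inf),
    }

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi, lo_open, hi_open) in self._RANGES.items():
            val = getattr(self, name)
            ok = (val > lo if lo_open else val >= lo) and (
                val < hi if hi_open else val <= hi
            )
            if not ok:
                raise ValidationError(
                    f"config parameter {name}={val!r} outside "
                    f"{'(' if lo_open else '['}{lo}, {hi}{')' if hi_open else ']'}"
                )
        if not self.k_off < self.k_on:
            raise ValidationError(
                f"k_off ({self.k_off}) must be smaller than k_on ({self.k_on})"
            )
        if not self.min_total_s < self.max_total_s:
            raise ValidationError("min_total_s must be smaller than max_total_s")
        g = self.svm_gamma
        if isinstance(g, str):
            if g != "median":
                raise ValidationError(f"svm_gamma must be 'median' or > 0, got {g!r}")
        elif not g > 0:
            raise ValidationError(f"svm_gamma must be 'median' or > 0, got {g!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise LoadError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise LoadError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
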