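"""Annotated synthetic EMG/bioimpedance recordings for benchmarking.

Real swallow corpora of this kind are clinical recordings that are not
redistributable, so the package ships a generator that emulates the
statistical structure the detector relies on:

* **swallows** — a band-limited submental EMG burst whose onset precedes the
  start of a smooth, asymmetric bioimpedance valley (piecewise raised-cosine
  descent and ascent). Valley depth ("maximum laryngeal elevation") and
  average descent slope ("speed of laryngeal elevation") are drawn from
  truncated normals calibrated to published cohort means and SDs for healthy
  subjects and dysphagia patients;
* **nonswallow confounders** — chew-like repetitive EMG bursts, and slow
  head-movement impedance excursions. Each kind has an *easy* variant that
  fails the stage-1 coincidence filter outright and a *hard* variant whose
  shallow/slow — yet condition-conforming — impedance dip coincides with EMG
  activity, so that only the trained classifier can reject it.

Depth and speed are coupled through a Gaussian copula (``rho = 0.85``):
deeper elevations are faster, which keeps descent durations in a physiologic
band while leaving both calibrated marginals intact. Truncation bounds are
handled by solving for the location parameter at which the *truncated* mean
equals the requested cohort mean, so large-sample means of the drawn
parameters match the cohort specification despite the sign constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats
from scipy.signal import butter, sosfiltfilt

from .io import EMBIRecording, EventAnnotation, ValidationError, validate_annotations

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "healthy_spec",
    "patient_spec",
    "synth_swallow_event",
    "synth_nonswallow_event",
    "generate_benchmark",
]

NONSWALLOW_KINDS = ("chew", "head_movement")


@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters of one simulated cohort.

    The four parameter means/SDs default to the published healthy-cohort
    values (ohm, ohm/s, s); :func:`patient_spec` swaps in the patient rows and
    degrades the EMG signal-to-noise ratio.
    """

    regime: str = "healthy"
    depth_mean: float = -1.416  # ohm
    depth_sd: float = 0.482
    speed_mean: float = -4.963  # ohm/s
    speed_sd: float = 1.901
    prep_mean: float = -0.192  # s
    prep_sd: float = 0.512
    closure_mean: float = -0.935  # s (magnitude = total valley duration)
    closure_sd: float = 0.512
    emg_snr_db: float = 20.0
    n_swallows: int = 30
    n_nonswallows: int = 60
    event_spacing_s: float = 4.5
    seed: int = 0
    fs: float = 1000.0
    # signal / noise model
    emg_noise_mv: float = 0.01
    bi_noise_ohm: float = 0.05
    bi_baseline_ohm: float = 40.0
    drift_amp_ohm: float = 0.15
    # confounder mix: fraction of nonswallows that pass the coincidence filter
    hard_fraction: float = 0.5
    # physiologic truncation of the parameter draws
    depth_cap_ohm: float = -0.45
    speed_cap_ohm_s: float = -0.8
    descent_min_s: float = 0.16
    descent_max_s: float = 1.6
    prep_min_s: float = -1.2
    prep_max_s: float = -0.02
    closure_cap_s: float = 2.4
    depth_speed_rho: float = 0.85

    def __post_init__(self) -> None:
        if self.regime not in ("healthy", "patient"):
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.depth_mean >= 0 or self.speed_mean >= 0:
            raise ValidationError("depth_mean and speed_mean must be negative")
        if min(self.depth_sd, self.speed_sd, self.prep_sd, self.closure_sd) < 0:
            raise ValidationError("standard deviations must be nonnegative")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not -1 < self.depth_speed_rho < 1:
            raise ValidationError("depth_speed_rho must lie in (-1, 1)")
        if self.depth_cap_ohm >= 0 or self.speed_cap_ohm_s >= 0:
            raise ValidationError("truncation caps must be negative")
        if not self.prep_min_s < self.prep_max_s < 0:
            raise ValidationError("need prep_min_s < prep_max_s < 0")
        if self.event_spacing_s <= self.max_event_extent_s():
            raise ValidationError(
                "event_spacing_s must exceed the maximum event extent "
                f"({self.max_event_extent_s():.2f} s)"
            )

    def max_event_extent_s(self) -> float:
        """Upper bound on any single event fragment, lead/tail pads included."""
        swallow = _PAD + (-self.prep_min_s) + self.closure_cap_s + _PAD
        head_easy = _PAD + 3.7 + _PAD
        return max(swallow, head_easy)


def healthy_spec(**overrides) -> CohortSpec:
    """Healthy-cohort defaults (deep, fast valleys; 20 dB EMG SNR)."""
    return CohortSpec(**({"regime": "healthy"} | overrides))


def patient_spec(**overrides) -> CohortSpec:
    """Dysphagia-patient defaults: shallower, slower, more variable valleys,
    wider preparation-time spread and 8 dB EMG SNR."""
    base = dict(
        regime="patient",
        depth_mean=-1.170,
        depth_sd=0.645,
        speed_mean=-4.253,
        speed_sd=2.488,
        prep_mean=0.022,
        prep_sd=8.360,
        closure_mean=-0.955,
        closure_sd=0.219,
        emg_snr_db=8.0,
    )
    return CohortSpec(**(base | overrides))


@dataclass(frozen=True)
class GroundTruth:
    """True landmarks and drawn parameter values of one synthesized event.

    Times are relative to the fragment start when produced by the
    ``synth_*_event`` functions and shifted to recording time by
    :func:`generate_benchmark`. Fields that do not apply to a given event
    kind are ``nan``.
    """

    annotation: EventAnnotation
    kind: str  # "swallow" | "chew" | "head_movement"
    hard: bool
    t_emg_start: float = float("nan")
    t_bi_start: float = float("nan")
    t_bi_min: float = float("nan")
    t_bi_end: float = float("nan")
    depth: float = float("nan")  # ohm
    speed: float = float("nan")  # ohm/s
    prep: float = float("nan")  # s
    closure: float = float("nan")  # s

    def shifted(self, dt: float) -> "GroundTruth":
        ann = self.annotation
        return replace(
            self,
            annotation=EventAnnotation(
                ann.label, ann.sublabel, ann.onset_s + dt, ann.offset_s + dt
            ),
            t_emg_start=self.t_emg_start + dt,
            t_bi_start=self.t_bi_start + dt,
            t_bi_min=self.t_bi_min + dt,
            t_bi_end=self.t_bi_end + dt,
        )


_PAD = 0.25  # lead/tail pad inside every event fragment, seconds


# ---------------------------------------------------------------------------
# calibrated parameter draws
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _mean_matched_loc(mean: float, sd: float, upper: float) -> float:
    """Location ``loc`` such that ``E[X | X <= upper] == mean`` for N(loc, sd).

    Requires ``mean < upper``; the truncated mean is strictly increasing in
    ``loc`` and approaches ``upper`` from below, so a root always exists.
    """
    if sd == 0:
        if mean > upper:
            raise ValidationError("degenerate draw above the truncation bound")
        return mean

    def excess(loc: float) -> float:
        b = (upper - loc) / sd
        return stats.truncnorm.mean(-np.inf, b, loc=loc, scale=sd) - mean

    return optimize.brentq(excess, mean, upper + 10 * sd, xtol=1e-10)


def _trunc_ppf(u: np.ndarray, mean: float, sd: float, upper: float) -> np.ndarray:
    if sd == 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    loc = _mean_matched_loc(mean, sd, upper)
    b = (upper - loc) / sd
    return stats.truncnorm.ppf(u, -np.inf, b, loc=loc, scale=sd)


def _draw_depth_speed(
    spec: CohortSpec, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Copula-coupled, mean-calibrated draws of (depth, speed).

    Pairs whose implied descent duration ``depth / speed`` falls outside
    ``[descent_min_s, descent_max_s]`` are redrawn jointly; thanks to the
    copula coupling this affects well under 2% of draws, so the calibrated
    means survive the rejection.
    """
    rho = spec.depth_speed_rho
    c = np.sqrt(1.0 - rho * rho)

    def draw(m: int) -> tuple[np.ndarray, np.ndarray]:
        z1 = rng.standard_normal(m)
        z2 = rho * z1 + c * rng.standard_normal(m)
        depth = _trunc_ppf(
            stats.norm.cdf(z1), spec.depth_mean, spec.depth_sd, spec.depth_cap_ohm
        )
        speed = _trunc_ppf(
            stats.norm.cdf(z2), spec.speed_mean, spec.speed_sd, spec.speed_cap_ohm_s
        )
        return depth, speed

    depth, speed = draw(size)
    for _ in range(200):
        d = depth / speed
        bad = (d < spec.descent_min_s) | (d > spec.descent_max_s)
        if not bad.any():
            break
        nd, ns = draw(int(bad.sum()))
        depth[bad] = nd
        speed[bad] = ns
    return depth, speed


def _rejection_interval(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """One draw of N(mean, sd) truncated into [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    return float(
        stats.truncnorm.rvs(
            (lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd, random_state=rng
        )
    )


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _raised_cosine_valley(
    t: np.ndarray, t_start: float, t_min: float, t_end: float, depth: float
) -> np.ndarray:
    """Smooth valley: half-cosine descent then half-cosine ascent, 0 at rest."""
    y = np.zeros_like(t)
    d_desc = t_min - t_start
    d_asc = t_end - t_min
    m = (t >= t_start) & (t < t_min)
    y[m] = depth * 0.5 * (1 - np.cos(np.pi * (t[m] - t_start) / d_desc))
    m = (t >= t_min) & (t <= t_end)
    y[m] = depth * 0.5 * (1 + np.cos(np.pi * (t[m] - t_min) / d_asc))
    return y


def _trapezoid(
    t: np.ndarray, t_on: float, t_off: float, ramp_up: float = 0.1, ramp_down: float = 0.15
) -> np.ndarray:
    """Amplitude modulation window: 0 outside [t_on, t_off], plateau 1."""
    ramp_up = min(ramp_up, (t_off - t_on) / 2)
    ramp_down = min(ramp_down, (t_off - t_on) / 2)
    w = np.zeros_like(t)
    m = (t >= t_on) & (t <= t_off)
    w[m] = 1.0
    ru = (t >= t_on) & (t < t_on + ramp_up)
    w[ru] = (t[ru] - t_on) / ramp_up
    rd = (t > t_off - ramp_down) & (t <= t_off)
    w[rd] = (t_off - t[rd]) / ramp_down
    return w


def _emg_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise (20 Hz to min(450, 0.45 fs) Hz)."""
    hi = min(450.0, 0.45 * fs)
    sos = butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def _burst_rms_mv(spec: CohortSpec, snr_offset_db: float = 0.0) -> float:
    return spec.emg_noise_mv * 10 ** ((spec.emg_snr_db + snr_offset_db) / 20.0)


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

def synth_swallow_event(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """One swallow fragment: ``(emg mV, bi ohm, ground truth)``.

    The bioimpedance fragment is the valley alone (0 at rest); the EMG
    fragment is the burst alone. Baseline noise, drift and the absolute
    impedance level are added by :func:`generate_benchmark`.
    """
    depth_a, speed_a = _draw_depth_speed(spec, rng, 1)
    depth, speed = float(depth_a[0]), float(speed_a[0])
    d_desc = depth / speed
    prep = _rejection_interval(
        rng, spec.prep_mean, spec.prep_sd, spec.prep_min_s, spec.prep_max_s
    )
    total = abs(
        _rejection_interval(
            rng,
            spec.closure_mean,
            spec.closure_sd,
            -spec.closure_cap_s,
            -(d_desc + 0.2),
        )
    )

    t_emg_start = _PAD
    t_bi_start = t_emg_start - prep
    t_bi_min = t_bi_start + d_desc
    t_bi_end = t_bi_start + total
    t_emg_end = t_bi_start + float(rng.uniform(0.5, 0.9)) * total
    t_emg_end = float(np.clip(t_emg_end, t_emg_start + 0.25, t_bi_end))
    frag_len = max(t_bi_end, t_emg_end) + _PAD

    n = int(round(frag_len * spec.fs))
    t = np.arange(n) / spec.fs
    bi = _raised_cosine_valley(t, t_bi_start, t_bi_min, t_bi_end, depth)
    emg = (
        _emg_carrier(n, spec.fs, rng)
        * _trapezoid(t, t_emg_start, t_emg_end)
        * _burst_rms_mv(spec)
    )
    gt = GroundTruth(
        annotation=EventAnnotation(
            "swallow",
            spec.regime,
            min(t_emg_start, t_bi_start) - 0.1,
            max(t_bi_end, t_emg_end) + 0.15,
        ),
        kind="swallow",
        hard=False,
        t_emg_start=t_emg_start,
        t_bi_start=t_bi_start,
        t_bi_min=t_bi_min,
        t_bi_end=t_bi_end,
        depth=depth,
        speed=speed,
        prep=prep,
        closure=total,
    )
    return emg, bi, gt


def synth_nonswallow_event(
    kind: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    hard: bool = False,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """One nonswallow fragment of the given kind.

    ``chew``: a train of three short EMG bursts; the *easy* variant carries
    only a sub-threshold impedance wobble, the *hard* variant a shallow but
    condition-conforming dip. ``head_movement``: an impedance excursion with
    silent EMG (*easy*: too slow and too long to pass the valley conditions)
    or, when *hard*, a tonic low-amplitude EMG with a shallow slow conforming
    dip starting after EMG onset.
    """
    if kind == "chew":
        return _synth_chew(spec, rng, hard)
    if kind == "head_movement":
        return _synth_head_movement(spec, rng, hard)
    raise ValidationError(f"unknown nonswallow kind {kind!r}")


def _synth_chew(spec, rng, hard):
    burst_dur, gap, n_bursts = 0.25, 0.45, 3
    starts = [_PAD + k * (burst_dur + gap) for k in range(n_bursts)]
    t_last_end = starts[-1] + burst_dur

    if hard:
        depth = float(rng.uniform(-0.8, -0.45))
        d_desc = float(rng.uniform(0.35, 0.6))
        total = float(rng.uniform(d_desc + 0.4, 1.8))
        t_bi_start = starts[0] + 0.15
    else:
        depth = float(rng.uniform(-0.15, -0.08))
        d_desc = float(rng.uniform(0.2, 0.4))
        total = float(rng.uniform(d_desc + 0.3, 1.2))
        t_bi_start = starts[0] + 0.1
    t_bi_min = t_bi_start + d_desc
    t_bi_end = t_bi_start + total

    frag_len = max(t_last_end, t_bi_end) + _PAD
    n = int(round(frag_len * spec.fs))
    t = np.arange(n) / spec.fs
    env = np.zeros_like(t)
    for s in starts:
        env += _trapezoid(t, s, s + burst_dur, ramp_up=0.06, ramp_down=0.08)
    emg = _emg_carrier(n, spec.fs, rng) * env * _burst_rms_mv(spec)
    bi = _raised_cosine_valley(t, t_bi_start, t_bi_min, t_bi_end, depth)
    gt = GroundTruth(
        annotation=EventAnnotation("nonswallow", "chew", _PAD - 0.1, frag_len - 0.1),
        kind="chew",
        hard=hard,
        t_bi_start=t_bi_start,
        t_bi_min=t_bi_min,
        t_bi_end=t_bi_end,
        depth=depth,
    )
    return emg, bi, gt


def _synth_head_movement(spec, rng, hard):
    if hard:
        t_emg_start = _PAD
        emg_dur = float(rng.uniform(1.0, 1.5))
        t_bi_start = t_emg_start + float(rng.uniform(0.1, 0.4))
        depth = float(rng.uniform(-1.0, -0.45))
        d_desc = float(rng.uniform(0.45, 0.8))
        total = float(rng.uniform(1.4, 2.4))
    else:
        t_emg_start = float("nan")
        emg_dur = 0.0
        t_bi_start = _PAD
        depth = float(rng.uniform(-1.5, -0.6))
        d_desc = float(rng.uniform(1.8, 2.4))
        total = float(rng.uniform(3.2, 3.7))
    t_bi_min = t_bi_start + d_desc
    t_bi_end = t_bi_start + total

    frag_len = t_bi_end + _PAD
    n = int(round(frag_len * spec.fs))
    t = np.arange(n) / spec.fs
    bi = _raised_cosine_valley(t, t_bi_start, t_bi_min, t_bi_end, depth)
    emg = np.zeros_like(t)
    if hard:
        emg = (
            _emg_carrier(n, spec.fs, rng)
            * _trapezoid(t, t_emg_start, t_emg_start + emg_dur)
            * _burst_rms_mv(spec, snr_offset_db=-4.0)
        )
    gt = GroundTruth(
        annotation=EventAnnotation(
            "nonswallow", "head_movement", 0.15, frag_len - 0.1
        ),
        kind="head_movement",
        hard=hard,
        t_emg_start=t_emg_start,
        t_bi_start=t_bi_start,
        t_bi_min=t_bi_min,
        t_bi_end=t_bi_end,
        depth=depth,
    )
    return emg, bi, gt


# ---------------------------------------------------------------------------
# whole recordings
# ---------------------------------------------------------------------------

def generate_benchmark(
    spec: CohortSpec,
    n_recordings: int,
    seed: int | None = None,
    duration_s: float | None = None,
) -> list[tuple[EMBIRecording, list[EventAnnotation], list[GroundTruth]]]:
    """Generate annotated recordings with interleaved events.

    Events are laid out on a slot grid (one slot of ``event_spacing_s`` per
    event, uniform jitter inside the slot), which guarantees non-overlapping
    annotations. Fully reproducible from *seed* (defaults to ``spec.seed``).
    """
    if n_recordings < 1:
        raise ValidationError("n_recordings must be >= 1")
    if seed is None:
        seed = spec.seed
    out = []
    lead = 1.5
    for r in range(n_recordings):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        kinds: list[tuple[str, bool]] = [("swallow", False)] * spec.n_swallows
        for k in range(spec.n_nonswallows):
            kind = NONSWALLOW_KINDS[k % 2]
            kinds.append((kind, bool(rng.random() < spec.hard_fraction)))
        order = rng.permutation(len(kinds))
        kinds = [kinds[i] for i in order]

        n_events = len(kinds)
        needed = lead + n_events * spec.event_spacing_s + lead
        dur = duration_s if duration_s is not None else max(needed, 10.0)
        if dur < needed:
            raise ValidationError(
                f"infeasible packing: {n_events} events need {needed:.1f} s, "
                f"got {dur:.1f} s"
            )
        n = int(round(dur * spec.fs))
        t = np.arange(n) / spec.fs
        emg = rng.normal(0.0, spec.emg_noise_mv, n)
        bi = spec.bi_baseline_ohm + rng.normal(0.0, spec.bi_noise_ohm, n)
        for _ in range(3):
            amp = spec.drift_amp_ohm * rng.uniform(0.2, 1.0) / 3
            period = rng.uniform(20.0, 120.0)
            bi += amp * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))

        annotations: list[EventAnnotation] = []
        truths: list[GroundTruth] = []
        for i, (kind, hard) in enumerate(kinds):
            if kind == "swallow":
                frag_emg, frag_bi, gt = synth_swallow_event(spec, rng)
            else:
                frag_emg, frag_bi, gt = synth_nonswallow_event(kind, spec, rng, hard)
            frag_len = len(frag_emg) / spec.fs
            slot_start = lead + i * spec.event_spacing_s
            slack = spec.event_spacing_s - frag_len - 0.1
            if slack < 0:
                raise ValidationError(
                    f"infeasible packing: fragment of {frag_len:.2f} s does not "
                    f"fit a {spec.event_spacing_s:.2f} s slot"
                )
            offset = slot_start + float(rng.uniform(0.0, slack))
            i0 = int(round(offset * spec.fs))
            emg[i0 : i0 + len(frag_emg)] += frag_emg
            bi[i0 : i0 + len(frag_bi)] += frag_bi
            gt = gt.shifted(i0 / spec.fs)
            annotations.append(gt.annotation)
            truths.append(gt)

        rec = EMBIRecording(
            subject_id=f"sim-{spec.regime}-{seed}-{r:03d}",
            fs=spec.fs,
            t=t,
            emg=emg,
            bi=bi,
            cohort_tag=spec.regime,
        )
        out.append((rec, validate_annotations(annotations), truths))
    return out
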