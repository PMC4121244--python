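# Methods

This note records the models, the defaults and the design decisions behind
`embidetect`, in the order signal flows through the pipeline.

## Signal model and preprocessing

A recording is two synchronized channels on one uniform time base
(default 1 kHz): submental surface EMG in mV and trans-cervical bioimpedance
in ohm. Preprocessing is fixed-role Butterworth filtering, zero-phase
(forward-backward) by default so that no landmark time is shifted:

| step | filter | default | rationale |
|---|---|---|---|
| EMG high-pass | order 4 | 20 Hz | removes DC/motion drift; standard sEMG practice |
| EMG envelope | rectify + order-2 low-pass | 10 Hz | nonnegative, positively homogeneous amplitude envelope for burst detection |
| BI smoothing | order-2 low-pass | 5 Hz | swallow valleys are sub-5 Hz; a 1 s wide, 1 ohm deep valley loses < 5% depth |

All cutoffs and orders live in `PipelineConfig` and are validated against
documented ranges at load time.

## EMG burst detection (stage-1 criterion 1)

A double-threshold detector on the envelope: open where the envelope holds
`mu + k_on*sigma` for ≥ `min_above_s`; close at the first sustained
(≥ `min_below_s`) excursion below `mu + k_off*sigma`; merge segments closer
than `max_gap_merge_s`; drop segments shorter than `min_duration_s`.

*Baseline estimation.* `mu`, `sigma` are pooled over every
`baseline_window_s` window whose mean envelope lies within the robust
(MAD-based) window-to-window spread of the minimum. Using only the single
quietest window biases both statistics low — the quietest window is quiet by
selection — which in practice parks the off-threshold inside the noise band
so that segments close too rarely and neighbouring events fuse into one
burst. Pooling removes that bias while still tolerating recordings that
start mid-activity.

*Defaults* (`k_on=4`, `k_off=1.5`, `min_above_s=0.05`, `min_below_s=0.2`,
`min_duration_s=0.2`, `max_gap_merge_s=0.2`): chosen on the synthetic
benchmark so that pure-noise recordings produce ≤ 1 false segment per
minute while bursts down to 8 dB SNR are still caught. Ties in the envelope
maximum resolve to the earliest sample.

*A caveat on threshold monotonicity.* Raising `k_on` shrinks or removes
onset regions, so with gap-merging disabled the segment count is monotone
non-increasing in `k_on`. With merging enabled this is not a theorem: a
higher onset threshold delays a segment's start, which can widen the gap to
its predecessor past `max_gap_merge_s` and split one merged segment into
two. The property is therefore tested in its provable (merge-free) form.

## Bioimpedance valleys (stage-1 criterion 2)

The smoothed BI trace is tiled with least-squares line pieces by bottom-up
piecewise linear approximation: start from short equal pieces (default
0.05 s; any initial piece whose own residual exceeds the tolerance is split
recursively, so the bound holds by construction), then repeatedly merge the
adjacent pair with the smallest merged maximum-absolute residual while that
residual stays ≤ ε (default 0.05 ohm). The scheme is offline, deterministic,
and every output piece satisfies the residual bound exactly.

Pieces are labelled descending / ascending / flat against a slope dead-band
(`flat_slope_ohm_s = 0.25`); a valley is a maximal descending run, at most
`max_flat_bottom_s = 0.5` s of flat bottom, then a maximal ascending run.
Landmarks: `BI_start` at the start of the descending run, `BI_min` at the
earliest signal minimum between the runs, `BI_end` at the end of the
ascending run. Depth is measured from the local value at `BI_start`, not
from a global baseline, so slow drift does not contaminate it. Candidate
valleys must pass physiological gates, all configurable: |depth| ≥ 0.3 ohm,
total duration in [0.2, 3.0] s, descent ≥ 0.1 s, mean descent slope
≤ −0.5 ohm/s. The published healthy means (−1.4 ohm at −5.0 ohm/s over
~0.3 s) pass these gates with wide margin; typical head-movement excursions
(slow, long) and chewing wobble (shallow) fail them.

## Pairing and swallowing parameters

EMG activity always precedes the impedance drop in a swallow, so a
(segment, valley) pair qualifies iff `t(EMG_start) ≤ t(BI_start) ≤
t(EMG_end) + grace_s` (grace 0.5 s). Bursts are served in temporal order;
each takes its deepest qualifying valley; each valley is used once.

Feature vector per candidate (ordered, fixed arity): maximum laryngeal
elevation `BI_min − BI_start` (ohm, negative), speed of laryngeal elevation
(that depth divided by descent duration, ohm/s, negative), preparation
duration `t(EMG_start) − t(BI_start)` (s, negative), extent of laryngeal
closure `t(BI_end) − t(BI_start)` (s), plus burst duration, envelope peak
and RMS, descent/ascent durations, ascent slope, and the EMG-to-valley
latency. Two sign/formula conventions deserve note: the preparation
duration is implemented with the sign that makes it negative when the
muscle burst leads (matching the reported cohort means), and the "extent"
parameter is implemented as the valley duration in seconds — the only
dimensionally consistent reading of the published definition, whose printed
form mixes ohms and seconds.

## Classification (stage 2)

A soft-margin SVM with RBF kernel over z-scored features (scaler fitted on
training candidates only). Defaults: `C = 1`; kernel width by the median
heuristic, `gamma = 1/(2 m²)` with `m` the median pairwise distance between
(up to 512 subsampled) standardized training points; decision threshold 0 on
the signed margin. Training candidates are labelled by whether their
`BI_min` falls inside an annotated swallow interval. Training requires at
least two examples per class and is deterministic given the seed.

## Evaluation

Event-level scoring: a swallow decision whose `BI_min` lies in an annotated
swallow interval is a TP (greedy one-to-one in time; duplicates are FP);
unmatched swallow intervals are FN; each annotated nonswallow interval is a
TN, or an FP if a swallow decision lands inside it; detections inside no
interval are FP. Nonswallow events must be explicit intervals so that
specificity has a defined denominator. Rates with zero denominator are NaN,
never 0.

Group comparisons use the two-sided Mann-Whitney U test (midrank ties),
exact by enumeration for tie-free samples with `n1 + n2 ≤ 12`, otherwise the
normal approximation with tie and continuity corrections; α = 0.05; four
parameters tested separately with no multiplicity correction, reported with
group means and SDs.

## Synthetic cohorts

The generator emulates the statistical structure the detector exploits; the
defaults are the study conditions for the benchmark.

*Swallows.* The BI valley is a piecewise raised cosine (independent
half-cosine descent and ascent), so the mean descent slope equals the drawn
speed exactly. The EMG burst is band-limited Gaussian noise (20 Hz to
min(450, 0.45·fs) Hz) under a trapezoidal envelope, with plateau RMS set by
the cohort SNR over the 0.01 mV baseline noise. Depth and speed are drawn
from truncated normals whose *location is solved (Brent) so the truncated
mean equals the cohort mean* — naive truncation at the physiologic bounds
(depth ≤ −0.45 ohm, speed ≤ −0.8 ohm/s) would bias the patient means by
more than their calibration tolerance. The two draws are coupled by a
Gaussian copula (ρ = 0.85; deeper elevations are faster), which keeps the
implied descent duration inside [0.16, 1.6] s for > 98% of pairs; the rare
violators are redrawn jointly, leaving the calibrated marginals essentially
intact (verified at design time against 3-SE bands at n = 1000).
Preparation time is truncated to [−1.2, −0.02] s: the EMG-leads convention
is a hard constraint of the pairing rule, and no negative-truncated normal
can reproduce the (slightly positive, enormously dispersed) published
patient mean, so depth and speed are the calibrated parameters and timing is
convention-bound. Total valley duration is a truncated draw from the
closure distribution, capped at 2.4 s.

*Confounders.* Chew: three 0.25 s bursts 0.45 s apart; easy variant with a
sub-threshold (≤ 0.15 ohm) BI wobble, hard variant with a shallow
(0.45–0.8 ohm) but condition-conforming dip starting after the first burst.
Head movement: easy variant is a deep but slow and long excursion with
silent EMG (fails both filter criteria); hard variant adds a tonic
low-amplitude burst preceding a shallow slow conforming dip. Half of the
confounders are hard by default: the original pipeline forwarded thousands
of stage-1 false positives to its classifier, and a benchmark whose
confounders all die at stage 1 would leave stage 2 untrained and untested.

*Cohorts.* Healthy: published healthy means/SDs, 20 dB SNR. Patient:
published patient means/SDs (shallower, slower, more variable), 8 dB SNR and
wider timing spread — the SNR and timing knobs are this package's own
operationalization of the harder patient detection problem; only the outcome
difference is published. Recordings interleave ~30 swallows and ~60
confounders on a 4.5 s slot grid with uniform jitter (annotations provably
non-overlapping), over gentle sinusoidal baseline drift (≤ 0.15 ohm,
20–120 s periods) and white measurement noise (0.05 ohm). Everything is
reproducible from one seed via spawned per-recording generators.

*What the generator does not model:* real EMBI noise spectra and artifact
families (electrode motion, ECG bleed-through), bolus-consistency effects
beyond mean shifts, penetration-specific morphology, and inter-subject
variability structure. Benchmark results therefore demonstrate the
pipeline's correctness and its behaviour under the stated statistical
conditions, not clinical performance.

## Benchmark protocol and problem sizes

The shipped benchmark uses 40 recordings per regime (~1200 swallows, ~2400
confounders), trained on the first 20 and scored on the held-out 20 —
the same shape as the original train/test protocol at roughly desk scale.
Stage-1 recall is measured over all 40 recordings before classification.
Generator calibration is checked on 1000 drawn events against 3-SE bands.
One full regime (generation + training + held-out scoring) takes ~30 s on a
single CPU.

## Numerical choices and degenerate inputs

- Zero-phase filtering throughout; envelope clipped at 0 after low-pass
  undershoot.
- Baseline sigma floored at 1e-9 mV so a featureless (constant) envelope
  yields no activity rather than everything-active.
- PLA ties (equal merge costs) resolve leftmost; equal envelope maxima and
  equal valley minima resolve earliest.
- A valley whose minimum coincides with its first or last sample, or whose
  ascent is non-positive, is discarded rather than emitted malformed.
- All-identical samples in the U test return p = 1 (no evidence) instead of
  a 0/0 tie correction.
- Recording time bases must be uniform within 1 ppm relative jitter; CSV
  round-trips are lossless to better than 1e-9.

## Known limitations

- The detector is offline (zero-phase filters, bottom-up PLA); it is not a
  causal/streaming implementation suitable for stimulation triggering.
- The exact feature list and detector constants of the original system are
  not published; this package's defaults are calibrated engineering choices,
  deliberately exposed in `PipelineConfig`.
- Specificity is only defined against explicitly annotated nonswallow
  intervals; free-running false-positive rates per unit time are not part of
  the contingency-table protocol.
- The SVM is trained per-benchmark; no cross-subject transfer claims are
  made or tested.
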