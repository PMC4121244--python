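"""Independent reference implementations used to cross-check the detectors.

These are deliberately naive (per-sample loops, explicit enumeration) and
share no segmentation logic with the package; they exist so the optimized
implementations can be verified against a transparent restatement of the same
rules.
"""

from __future__ import annotations

from itertools import combinations
from math import ceil

import numpy as np

from embidetect.emg import SIGMA_FLOOR_MV, DoubleThresholdParams, estimate_baseline


def naive_emg_segments(
    env: np.ndarray, fs: float, params: DoubleThresholdParams
) -> list[tuple[int, int]]:
    """Per-sample restatement of the double-threshold segmentation rules.

    Thresholds are taken from the package's baseline estimator so the
    comparison isolates the segmentation state machine itself. Returns raw
    sample-index pairs ``[open, close)`` after merging and duration filtering.
    """
    env = np.asarray(env, dtype=float)
    n = len(env)
    mu, sigma = estimate_baseline(env, fs, params)
    sigma = max(sigma, SIGMA_FLOOR_MV)
    thr_on = mu + params.k_on * sigma
    thr_off = mu + params.k_off * sigma
    n_above = max(1, ceil(params.min_above_s * fs))
    n_below = max(1, ceil(params.min_below_s * fs))

    raw: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if env[i] < thr_on:
            i += 1
            continue
        j = i
        while j < n and env[j] >= thr_on:
            j += 1
        if j - i < n_above:
            i = j
            continue
        # opened at i: close at the first stretch of n_below samples below
        # the off threshold, then resume after that below-stretch ends
        close = None
        k = j
        while k <= n - n_below:
            if all(env[k + m] < thr_off for m in range(n_below)):
                close = k
                break
            k += 1
        if close is None:
            raw.append((i, n))
            i = n
        else:
            raw.append((i, close))
            e = close
            while e < n and env[e] < thr_off:
                e += 1
            i = e

    merged: list[list[int]] = []
    for s, e in raw:
        if merged and (s - merged[-1][1]) / fs < params.max_gap_merge_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    n_min = ceil(params.min_duration_s * fs)
    return [(s, e) for s, e in merged if e - s >= n_min]


def naive_valley_minima(
    y: np.ndarray, min_depth: float, merge_gap: int = 64
) -> list[int]:
    """Brute-force valley finder for traces resting at baseline 0.

    Every connected region where the trace dips below ``-min_depth`` is one
    valley; regions separated by fewer than ``merge_gap`` samples are the same
    valley (noise chatter around the threshold crossing). Returns the index of
    the earliest minimum of each region.
    """
    y = np.asarray(y, dtype=float)
    below = y < -min_depth
    regions: list[list[int]] = []
    i = 0
    n = len(y)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if regions and i - regions[-1][1] < merge_gap:
            regions[-1][1] = j
        else:
            regions.append([i, j])
        i = j
    return [i + int(np.argmin(y[i:j])) for i, j in regions]


def enumerate_u_test(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by full enumeration (tie-free input).

    Returns ``(U of group a, two-sided p)`` with the two-sided p defined as
    twice the smaller one-sided tail (observed value included), capped at 1.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n1 = len(a)

    def u_stat(group_a: list[float], group_b: list[float]) -> int:
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    us = [
        u_stat([pooled[i] for i in idx], [pooled[i] for i in range(len(pooled)) if i not in idx])
        for idx in map(set, combinations(range(len(pooled)), n1))
    ]
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return float(u_obs), float(min(1.0, 2 * min(p_low, p_high)))
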