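"""Bioimpedance segmentation: piecewise linear approximation and valley extraction.

During the pharyngeal phase of a swallow the larynx and hyoid move up and
forward, the pharyngeal cavity fills with tissue and the trans-cervical
impedance drops — the bioimpedance trace shows a valley whose depth and
steepness track laryngeal elevation. The trace is tiled with least-squares
line pieces whose maximum absolute residual stays below a tolerance
``epsilon`` (bottom-up merging, offline and deterministic). A valley is a
maximal run of descending pieces, optionally a short flat bottom, then a
maximal run of ascending pieces; candidate valleys must additionally satisfy
physiological conditions on depth, duration and descent slope.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .io import ValidationError

__all__ = [
    "PLASegment",
    "BIValley",
    "ValleyConditions",
    "pla_approximate",
    "detect_bi_valleys",
]


@dataclass(frozen=True)
class PLASegment:
    """One least-squares line piece over samples ``[i_start, i_end)``.

    ``slope`` is in ohm/s and ``intercept`` in ohm, with time measured as
    ``i / fs`` from the first sample of the signal passed to
    :func:`pla_approximate`.
    """

    i_start: int
    i_end: int
    slope: float
    intercept: float
    max_abs_err: float


@dataclass(frozen=True)
class BIValley:
    """A condition-checked valley with its three landmarks (seconds / ohm)."""

    t_start: float
    t_min: float
    t_end: float
    bi_at_start: float
    bi_at_min: float
    bi_at_end: float
    depth: float  # bi_at_min - bi_at_start, negative
    descent_slope: float  # ohm/s, negative
    ascent_slope: float  # ohm/s, positive


@dataclass(frozen=True)
class ValleyConditions:
    """Physiological gates a candidate valley must pass.

    ``max_descent_slope_ohm_s`` is an upper bound on the (negative) average
    descent slope: the drop must be at least that steep.
    """

    min_depth_ohm: float = 0.3
    min_total_s: float = 0.2
    max_total_s: float = 3.0
    min_descent_s: float = 0.1
    max_descent_slope_ohm_s: float = -0.5

    def __post_init__(self) -> None:
        if self.min_depth_ohm <= 0:
            raise ValidationError("min_depth_ohm must be positive (applied to |depth|)")
        if not 0 < self.min_total_s < self.max_total_s:
            raise ValidationError("need 0 < min_total_s < max_total_s")
        if self.min_descent_s <= 0:
            raise ValidationError("min_descent_s must be positive")
        if self.max_descent_slope_ohm_s >= 0:
            raise ValidationError("max_descent_slope_ohm_s must be negative")


def pla_approximate(
    bi_smoothed: np.ndarray,
    fs: float,
    epsilon: float,
    piece_s: float = 0.05,
) -> list[PLASegment]:
    """Tile the signal with line pieces of max absolute residual <= *epsilon*.

    Bottom-up scheme: start from short equal pieces (length ``piece_s``) and
    greedily merge the adjacent pair whose merged fit has the smallest maximum
    residual, while that residual stays within *epsilon*. Deterministic; ties
    resolve to the leftmost pair.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    y = np.asarray(bi_smoothed, dtype=float)
    n = len(y)
    if n < 2:
        raise ValidationError("signal must have at least 2 samples")
    x = np.arange(n, dtype=float) / fs

    # prefix sums for O(1) least-squares line fits over [i, j)
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))

    def fit(i: int, j: int) -> tuple[float, float]:
        m = j - i
        if m == 1:  # degenerate single-sample piece: flat line through it
            return 0.0, float(y[i])
        sx = cx[j] - cx[i]
        sy = cy[j] - cy[i]
        sxx = cxx[j] - cxx[i]
        sxy = cxy[j] - cxy[i]
        denom = m * sxx - sx * sx
        slope = (m * sxy - sx * sy) / denom
        return slope, (sy - slope * sx) / m

    def max_err(i: int, j: int) -> float:
        slope, b = fit(i, j)
        return float(np.max(np.abs(y[i:j] - (slope * x[i:j] + b))))

    step = max(2, int(round(piece_s * fs)))
    coarse = list(range(0, n, step))
    if n - coarse[-1] < 2:  # absorb a trailing stub into the last piece
        coarse.pop()
    coarse.append(n)

    # initial pieces must themselves satisfy the residual bound: split any
    # violating piece in half (a 2-sample piece always fits exactly)
    bounds = [0]
    stack = [(coarse[k], coarse[k + 1]) for k in range(len(coarse) - 2, -1, -1)]
    while stack:
        i, j = stack.pop()
        if j - i <= 2 or max_err(i, j) <= epsilon:
            bounds.append(j)
        else:
            # a 3-sample violator degrades to 1 + 2 samples; both fit exactly
            mid = i + 1 if j - i == 3 else (i + j) // 2
            stack.append((mid, j))
            stack.append((i, mid))
    npc = len(bounds) - 1

    start = [bounds[k] for k in range(npc)]
    end = [bounds[k + 1] for k in range(npc)]
    prv = list(range(-1, npc - 1))
    nxt = list(range(1, npc + 1))
    nxt[-1] = -1
    alive = [True] * npc
    version = [0] * npc

    heap: list[tuple[float, int, int, int, int]] = []

    def push(left: int) -> None:
        right = nxt[left]
        if right == -1:
            return
        cost = max_err(start[left], end[right])
        heapq.heappush(heap, (cost, left, version[left], right, version[right]))

    for k in range(npc - 1):
        push(k)

    while heap:
        cost, left, vl, right, vr = heapq.heappop(heap)
        if (
            not alive[left]
            or not alive[right]
            or version[left] != vl
            or version[right] != vr
            or nxt[left] != right
        ):
            continue
        if cost > epsilon:
            break
        # merge right into left
        end[left] = end[right]
        alive[right] = False
        nxt[left] = nxt[right]
        if nxt[left] != -1:
            prv[nxt[left]] = left
        version[left] += 1
        if prv[left] != -1:
            push(prv[left])
        push(left)

    segments = []
    k = 0
    while k != -1:
        if alive[k]:
            slope, b = fit(start[k], end[k])
            segments.append(
                PLASegment(
                    i_start=start[k],
                    i_end=end[k],
                    slope=slope,
                    intercept=b,
                    max_abs_err=max_err(start[k], end[k]),
                )
            )
        k = nxt[k]
    return segments


def detect_bi_valleys(
    segments: list[PLASegment],
    bi_smoothed: np.ndarray,
    fs: float,
    cond: ValleyConditions | None = None,
    flat_slope_ohm_s: float = 0.25,
    max_flat_bottom_s: float = 0.5,
    t0: float = 0.0,
) -> list[BIValley]:
    """Extract condition-checked valleys from a PLA tiling.

    Pieces are labelled descending / ascending / flat by comparing their slope
    with ``flat_slope_ohm_s``; a valley is a maximal descending run, at most
    ``max_flat_bottom_s`` of flat bottom, then a maximal ascending run. The
    minimum landmark is the earliest signal minimum between the two runs.
    """
    if cond is None:
        cond = ValleyConditions()
    if not segments:
        return []
    y = np.asarray(bi_smoothed, dtype=float)

    def label(seg: PLASegment) -> str:
        if seg.slope <= -flat_slope_ohm_s:
            return "D"
        if seg.slope >= flat_slope_ohm_s:
            return "U"
        return "F"

    labels = [label(s) for s in segments]
    dur = [(s.i_end - s.i_start) / fs for s in segments]
    valleys: list[BIValley] = []

    i = 0
    m = len(segments)
    while i < m:
        if labels[i] != "D":
            i += 1
            continue
        j = i
        while j + 1 < m and labels[j + 1] == "D":
            j += 1
        k = j + 1
        flat = 0.0
        while k < m and labels[k] == "F" and flat + dur[k] <= max_flat_bottom_s:
            flat += dur[k]
            k += 1
        if k < m and labels[k] == "U":
            last = k
            while last + 1 < m and labels[last + 1] == "U":
                last += 1
            v = _build_valley(
                y, fs, t0, segments[i].i_start, segments[last].i_end, cond
            )
            if v is not None:
                valleys.append(v)
            i = last + 1
        else:
            i = max(j + 1, k)
    return valleys


def _build_valley(
    y: np.ndarray,
    fs: float,
    t0: float,
    i_start: int,
    i_end: int,
    cond: ValleyConditions,
) -> BIValley | None:
    i_last = i_end - 1
    i_min = i_start + int(np.argmin(y[i_start:i_end]))  # earliest minimum on ties
    t_start = t0 + i_start / fs
    t_min = t0 + i_min / fs
    t_end = t0 + i_last / fs
    if not t_start < t_min < t_end:
        return None
    bi_start = float(y[i_start])
    bi_min = float(y[i_min])
    bi_end = float(y[i_last])
    depth = bi_min - bi_start
    total = t_end - t_start
    descent = t_min - t_start
    descent_slope = depth / descent
    ascent_slope = (bi_end - bi_min) / (t_end - t_min)
    if depth >= 0 or ascent_slope <= 0:
        return None
    if -depth < cond.min_depth_ohm:
        return None
    if not cond.min_total_s <= total <= cond.max_total_s:
        return None
    if descent < cond.min_descent_s:
        return None
    if descent_slope > cond.max_descent_slope_ohm_s:
        return None
    return BIValley(
        t_start=t_start,
        t_min=t_min,
        t_end=t_end,
        bi_at_start=bi_start,
        bi_at_min=bi_min,
        bi_at_end=bi_end,
        depth=depth,
        descent_slope=descent_slope,
        ascent_slope=ascent_slope,
    )
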