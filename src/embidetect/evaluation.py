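"""Event-level scoring and between-group statistics.

Detections are scored against annotated events through a 2x2 contingency
table: a detected swallow whose valley-minimum landmark falls inside an
annotated swallow interval is a true positive (matched one-to-one, greedily in
time); annotated nonswallow intervals count as true negatives unless a swallow
decision lands inside them. Group comparisons of the swallowing-related
parameters use the two-sided Mann-Whitney U test at alpha = 0.05, one test per
parameter with no multiplicity correction (four separate tests, reported with
group means and SDs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventAnnotation, ValidationError
from .pipeline import DetectedEvent, SwallowParameters, LABEL_SWALLOW, LABEL_NONSWALLOW

__all__ = [
    "ConfusionTable",
    "UTestResult",
    "match_events",
    "mann_whitney_u",
    "compare_groups",
    "MAIN_PARAMETERS",
]

#: The four swallowing-related parameters compared between groups.
MAIN_PARAMETERS = (
    "duration_preparation",
    "extent_laryngeal_closure",
    "max_laryngeal_elevation",
    "speed_laryngeal_elevation",
)


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts with rates derived on access.

    Rates with a zero denominator are reported as ``nan``, never as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @staticmethod
    def _rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return self._rate(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn)

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def match_events(
    detected: list[DetectedEvent], truth: list[EventAnnotation]
) -> ConfusionTable:
    """Score swallow decisions against annotated swallow/nonswallow intervals.

    Matching key is the valley-minimum time of each swallow-decision event.
    Swallow intervals are matched one-to-one greedily in time (duplicates are
    false positives); detections inside no annotated interval are also false
    positives; each annotated nonswallow interval contributes one true
    negative, or one false positive if at least one swallow decision lands
    inside it.
    """
    swallows = sorted(
        (e for e in truth if e.label == LABEL_SWALLOW), key=lambda e: e.onset_s
    )
    nonswallows = sorted(
        (e for e in truth if e.label == LABEL_NONSWALLOW), key=lambda e: e.onset_s
    )
    hits = [False] * len(swallows)
    flagged = [False] * len(nonswallows)
    extra_fp = 0
    decided = sorted(
        (d for d in detected if d.decision == LABEL_SWALLOW),
        key=lambda d: d.candidate.valley.t_min,
    )
    for det in decided:
        t = det.candidate.valley.t_min
        i = next((k for k, iv in enumerate(swallows) if iv.contains(t)), None)
        if i is not None:
            if hits[i]:
                extra_fp += 1
            else:
                hits[i] = True
            continue
        j = next((k for k, iv in enumerate(nonswallows) if iv.contains(t)), None)
        if j is not None:
            if flagged[j]:
                extra_fp += 1
            else:
                flagged[j] = True
        else:
            extra_fp += 1
    tp = sum(hits)
    fp = sum(flagged) + extra_fp
    return ConfusionTable(
        tp=tp, fp=fp, fn=len(swallows) - tp, tn=len(nonswallows) - sum(flagged)
    )


@dataclass(frozen=True)
class UTestResult:
    """Two-sided Mann-Whitney U result; ``u`` is the U statistic of group A."""

    u: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx"


#: Largest combined sample size for which the tie-free exact null
#: distribution is enumerated rather than normal-approximated.
EXACT_N_MAX = 12


def mann_whitney_u(group_a, group_b) -> UTestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    The exact null distribution is used for small tie-free samples
    (``n1 + n2 <= 12``); otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (len(a) + len(b) <= EXACT_N_MAX) and not has_ties
    if np.ptp(combined) == 0:
        # all observations identical: no evidence of any shift
        return UTestResult(
            u=len(a) * len(b) / 2,
            p=1.0,
            n1=len(a),
            n2=len(b),
            method="normal_approx",
        )
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return UTestResult(
        u=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        n1=len(a),
        n2=len(b),
        method="exact" if exact else "normal_approx",
    )


def compare_groups(
    params_a: list[SwallowParameters],
    params_b: list[SwallowParameters],
    parameters: tuple[str, ...] = MAIN_PARAMETERS,
) -> pd.DataFrame:
    """Per-parameter group comparison: means, SDs and the U test.

    Returns a frame with one row per parameter in the layout
    ``parameter, mean_a, sd_a, mean_b, sd_b, u, p, method``.
    """
    if not params_a or not params_b:
        raise ValidationError("both groups must be non-empty")
    rows = []
    for name in parameters:
        va = np.array([getattr(p, name) for p in params_a], dtype=float)
        vb = np.array([getattr(p, name) for p in params_b], dtype=float)
        res = mann_whitney_u(va, vb)
        rows.append(
            {
                "parameter": name,
                "mean_a": va.mean(),
                "sd_a": va.std(ddof=1) if len(va) > 1 else float("nan"),
                "mean_b": vb.mean(),
                "sd_b": vb.std(ddof=1) if len(vb) > 1 else float("nan"),
                "u": res.u,
                "p": res.p,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
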