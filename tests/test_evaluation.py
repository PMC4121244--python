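import numpy as np
import pytest

from embidetect.bi import BIValley
from embidetect.emg import EMGActivitySegment
from embidetect.evaluation import (
    ConfusionTable,
    compare_groups,
    mann_whitney_u,
    match_events,
)
from embidetect.io import EventAnnotation, ValidationError
from embidetect.pipeline import DetectedEvent, SwallowCandidate, extract_features


def _detected(t_min, decision="swallow"):
    v = BIValley(
        t_start=t_min - 0.3,
        t_min=t_min,
        t_end=t_min + 0.6,
        bi_at_start=40.0,
        bi_at_min=39.0,
        bi_at_end=40.0,
        depth=-1.0,
        descent_slope=-3.3,
        ascent_slope=1.7,
    )
    seg = EMGActivitySegment(t_min - 0.5, t_min, t_min + 0.4, 0.1, 0.05)
    cand = SwallowCandidate(seg, v)
    return DetectedEvent(cand, extract_features(cand), decision, 1.0)


def _truth(label, onset, offset, sub=""):
    return EventAnnotation(label, sub, onset, offset)


class TestConfusionTable:
    def test_printed_patient_rates(self):
        """Counts chosen to reproduce the published patient operating point."""
        t = ConfusionTable(tp=359, fn=68, tn=1293, fp=234)
        assert round(100 * t.sensitivity, 1) == 84.1
        assert round(100 * t.specificity, 1) == 84.7
        assert round(100 * t.accuracy, 1) == 84.5

    def test_zero_denominator_is_nan_not_zero(self):
        t = ConfusionTable(tp=0, fp=0, fn=0, tn=5)
        assert np.isnan(t.sensitivity)
        assert t.specificity == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionTable(-1, 0, 0, 0)


class TestMatchEvents:
    def _truthset(self, n_sw=10, n_ns=10):
        events = [_truth("swallow", 10 * k, 10 * k + 2) for k in range(n_sw)]
        events += [
            _truth("nonswallow", 10 * k + 5, 10 * k + 7, "chew") for k in range(n_ns)
        ]
        return events

    def test_perfect_detection(self):
        truth = self._truthset()
        detected = [_detected(10 * k + 1.0) for k in range(10)]
        t = match_events(detected, truth)
        assert (t.tp, t.fp, t.fn, t.tn) == (10, 0, 0, 10)
        assert t.sensitivity == 1.0 and t.specificity == 1.0

    def test_zero_detections(self):
        t = match_events([], self._truthset())
        assert t.sensitivity == 0.0
        assert t.specificity == 1.0

    def test_duplicate_detection_is_false_positive(self):
        truth = self._truthset(n_sw=1, n_ns=1)
        detected = [_detected(1.0), _detected(1.5)]
        t = match_events(detected, truth)
        assert (t.tp, t.fp) == (1, 1)

    def test_detection_in_nonswallow_interval_flips_tn_to_fp(self):
        truth = self._truthset(n_sw=1, n_ns=1)
        t = match_events([_detected(6.0)], truth)
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 1, 1, 0)

    def test_stray_detection_counts_fp(self):
        truth = self._truthset(n_sw=1, n_ns=1)
        t = match_events([_detected(900.0)], truth)
        assert t.fp == 1

    def test_nonswallow_decisions_ignored(self):
        truth = self._truthset(n_sw=1, n_ns=1)
        t = match_events([_detected(6.0, decision="nonswallow")], truth)
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 1, 1)

    def test_truth_events_partition(self, rng):
        """tp+fn covers every annotated swallow, tn + in-interval fp every nonswallow."""
        truth = self._truthset(7, 9)
        detected = [_detected(float(x)) for x in rng.uniform(0, 100, 20)]
        t = match_events(detected, truth)
        assert t.tp + t.fn == 7
        assert t.tn <= 9 and t.tp <= 7


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_complete_separation_tiny_p(self):
        res = mann_whitney_u(np.arange(1, 9), np.arange(101, 109))
        assert res.p < 0.001
        assert res.method == "normal_approx"  # n1+n2 = 16 > exact cutoff

    def test_minimal_groups(self):
        res = mann_whitney_u([1.0], [2.0])
        assert res.p == 1.0
        assert 0 <= res.u <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_exact_branch_equals_enumeration(self):
        """Exact p matches full enumeration for every group size up to 6."""
        from _oracles import enumerate_u_test

        rng = np.random.default_rng(7)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                vals = rng.permutation(100)[: n1 + n2].astype(float)
                a, b = vals[:n1], vals[n1:]
                res = mann_whitney_u(a, b)
                u_exp, p_exp = enumerate_u_test(a, b)
                assert res.method == "exact"
                assert res.u == pytest.approx(u_exp)
                assert res.p == pytest.approx(p_exp, abs=1e-12), (n1, n2)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays near nominal (2000 reps)."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            if mann_whitney_u(a, b).p <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_null_p_values_rarely_extreme(self):
        """Two draws from one distribution: p > 0.001 in >= 99% of 200 reps."""
        rng = np.random.default_rng(7)
        ok = sum(
            mann_whitney_u(rng.normal(size=50), rng.normal(size=50)).p > 0.001
            for _ in range(200)
        )
        assert ok >= 198


class TestCompareGroups:
    @staticmethod
    def _params_from(rng, depth_mean, depth_sd, speed_mean, speed_sd, n):
        from embidetect.pipeline import SwallowParameters

        out = []
        for _ in range(n):
            depth = rng.normal(depth_mean, depth_sd)
            speed = rng.normal(speed_mean, speed_sd)
            out.append(
                SwallowParameters(
                    max_laryngeal_elevation=depth,
                    speed_laryngeal_elevation=speed,
                    duration_preparation=rng.normal(-0.2, 0.5),
                    extent_laryngeal_closure=abs(rng.normal(0.94, 0.3)),
                    emg_duration_s=1.0,
                    emg_peak_mv=0.1,
                    emg_rms_mv=0.05,
                    descent_duration_s=0.3,
                    ascent_duration_s=0.7,
                    ascent_slope_ohm_s=1.5,
                    emg_to_valley_latency_s=0.2,
                )
            )
        return out

    def test_cohort_difference_detected(self):
        """Healthy vs patient depth/speed distributions separate at alpha=0.05."""
        rng = np.random.default_rng(7)
        healthy = self._params_from(rng, -1.416, 0.482, -4.963, 1.901, 300)
        patient = self._params_from(rng, -1.170, 0.645, -4.253, 2.488, 300)
        table = compare_groups(healthy, patient).set_index("parameter")
        assert table.loc["max_laryngeal_elevation", "p"] <= 0.05
        assert table.loc["speed_laryngeal_elevation", "p"] <= 0.05

    def test_single_observation_groups(self):
        rng = np.random.default_rng(1)
        a = self._params_from(rng, -1.4, 0.5, -5.0, 1.9, 1)
        b = self._params_from(rng, -1.4, 0.5, -5.0, 1.9, 1)
        table = compare_groups(a, b)
        assert (table["p"] == 1.0).all()
        assert len(table) == 4
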