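import numpy as np
import pytest

from embidetect import (
    SwallowDetector,
    generate_benchmark,
    healthy_spec,
    patient_spec,
    synth_nonswallow_event,
    synth_swallow_event,
)
from embidetect.evaluation import compare_groups
from embidetect.io import ValidationError
from embidetect.pipeline import SwallowParameters
from embidetect.synthetic import CohortSpec


def _draw_params(spec, n, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        _, _, gt = synth_swallow_event(spec, rng)
        rows.append(gt)
    return rows


class TestSpecValidation:
    def test_positive_depth_mean_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec(depth_mean=1.0)

    def test_spacing_must_exceed_event_extent(self):
        with pytest.raises(ValidationError, match="spacing"):
            healthy_spec(event_spacing_s=2.0)

    def test_unknown_nonswallow_kind_rejected(self):
        with pytest.raises(ValidationError):
            synth_nonswallow_event("cough", healthy_spec(), np.random.default_rng(0))


class TestSwallowEvents:
    def test_landmark_ordering_and_precedence(self):
        rng = np.random.default_rng(3)
        spec = healthy_spec()
        for _ in range(50):
            _, _, gt = synth_swallow_event(spec, rng)
            # muscle activity commences prior to the drop in impedance
            assert gt.t_emg_start < gt.t_bi_start < gt.t_bi_min < gt.t_bi_end
            assert gt.depth < 0 and gt.speed < 0 and gt.prep < 0

    def test_drawn_speed_equals_mean_descent_slope(self):
        rng = np.random.default_rng(4)
        _, bi, gt = synth_swallow_event(healthy_spec(), rng)
        assert gt.speed == pytest.approx(gt.depth / (gt.t_bi_min - gt.t_bi_start))

    def test_valley_waveform_reaches_drawn_depth(self):
        rng = np.random.default_rng(5)
        _, bi, gt = synth_swallow_event(healthy_spec(), rng)
        assert bi.min() == pytest.approx(gt.depth, rel=1e-3)

    def test_determinism_under_fixed_rng(self):
        spec = healthy_spec()
        e1, b1, g1 = synth_swallow_event(spec, np.random.default_rng(9))
        e2, b2, g2 = synth_swallow_event(spec, np.random.default_rng(9))
        np.testing.assert_array_equal(e1, e2)
        np.testing.assert_array_equal(b1, b2)
        assert g1 == g2

    @pytest.mark.parametrize("make_spec", [healthy_spec, patient_spec])
    def test_calibration_of_drawn_means(self, make_spec):
        """Large-sample drawn depth/speed means match the cohort means (3 SE)."""
        spec = make_spec()
        truths = _draw_params(spec, 1000, seed=11)
        depth = np.mean([g.depth for g in truths])
        speed = np.mean([g.speed for g in truths])
        assert abs(depth - spec.depth_mean) < 3 * spec.depth_sd / np.sqrt(1000)
        assert abs(speed - spec.speed_mean) < 3 * spec.speed_sd / np.sqrt(1000)


class TestNonswallowEvents:
    def test_easy_chew_produces_no_stage1_candidate(self):
        rng = np.random.default_rng(21)
        spec = healthy_spec(n_swallows=0, n_nonswallows=1, hard_fraction=0.0)
        ds = generate_benchmark(spec, 1, seed=21)
        assert SwallowDetector().stage1_candidates(ds[0][0]) == []

    def test_silent_head_movement_produces_no_candidate(self):
        # a 1-ohm dip without any EMG burst fails the first filter criterion
        rng = np.random.default_rng(22)
        emg, bi, gt = synth_nonswallow_event("head_movement", healthy_spec(), rng)
        assert np.all(emg == 0)
        assert gt.annotation.label == "nonswallow"

    def test_hard_confounders_pass_stage1(self):
        spec = healthy_spec(n_swallows=0, n_nonswallows=4, hard_fraction=1.0)
        ds = generate_benchmark(spec, 1, seed=23)
        cands = SwallowDetector().stage1_candidates(ds[0][0])
        assert len(cands) >= 2

    def test_determinism(self):
        import dataclasses

        spec = healthy_spec()
        for kind in ("chew", "head_movement"):
            e1, b1, g1 = synth_nonswallow_event(kind, spec, np.random.default_rng(8))
            e2, b2, g2 = synth_nonswallow_event(kind, spec, np.random.default_rng(8))
            np.testing.assert_array_equal(e1, e2)
            np.testing.assert_array_equal(b1, b2)
            assert g1.annotation == g2.annotation
            d1, d2 = dataclasses.asdict(g1), dataclasses.asdict(g2)
            for key in d1:
                if isinstance(d1[key], float):
                    np.testing.assert_allclose(d1[key], d2[key], equal_nan=True)


class TestBenchmarkGeneration:
    def test_event_count_conservation(self):
        spec = healthy_spec(n_swallows=10, n_nonswallows=5)
        ds = generate_benchmark(spec, 3, seed=31)
        swallows = [
            e for _, events, _ in ds for e in events if e.label == "swallow"
        ]
        assert len(swallows) == 30

    def test_reproducible_from_seed(self):
        spec = healthy_spec(n_swallows=3, n_nonswallows=3)
        r1, e1, _ = generate_benchmark(spec, 1, seed=32)[0]
        r2, e2, _ = generate_benchmark(spec, 1, seed=32)[0]
        np.testing.assert_array_equal(r1.emg, r2.emg)
        np.testing.assert_array_equal(r1.bi, r2.bi)
        assert e1 == e2

    def test_truth_landmarks_inside_annotations(self):
        spec = healthy_spec(n_swallows=5, n_nonswallows=5)
        for _, events, truths in generate_benchmark(spec, 2, seed=33):
            for gt in truths:
                if gt.kind == "swallow":
                    assert gt.annotation.contains(gt.t_bi_min)
                    assert gt.annotation.contains(gt.t_emg_start)
                    assert gt.annotation.onset_s <= gt.t_bi_end <= gt.annotation.offset_s

    def test_infeasible_packing_rejected(self):
        spec = healthy_spec(n_swallows=20, n_nonswallows=20)
        with pytest.raises(ValidationError, match="packing"):
            generate_benchmark(spec, 1, seed=34, duration_s=30)

    def test_regimes_differ_detectably(self):
        """Healthy vs patient drawn parameters separate in depth and speed."""
        h = _draw_params(healthy_spec(), 300, seed=7)
        p = _draw_params(patient_spec(), 300, seed=8)

        def to_params(gts):
            return [
                SwallowParameters(
                    max_laryngeal_elevation=g.depth,
                    speed_laryngeal_elevation=g.speed,
                    duration_preparation=g.prep,
                    extent_laryngeal_closure=g.closure,
                    emg_duration_s=0.0,
                    emg_peak_mv=0.0,
                    emg_rms_mv=0.0,
                    descent_duration_s=g.depth / g.speed,
                    ascent_duration_s=g.closure - g.depth / g.speed,
                    ascent_slope_ohm_s=1.0,
                    emg_to_valley_latency_s=-g.prep,
                )
                for g in gts
            ]

        table = compare_groups(to_params(h), to_params(p)).set_index("parameter")
        assert table.loc["max_laryngeal_elevation", "p"] <= 0.05
        assert table.loc["speed_laryngeal_elevation", "p"] <= 0.05
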