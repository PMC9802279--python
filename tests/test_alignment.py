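import numpy as np
import pytest

import matecalcium as mc
from matecalcium.alignment import (
    binarize_behavior,
    concatenate_matrices,
)
from matecalcium.extraction import ActivityTrace


def trace_from(x, rid="t", nid="N", rate=5.0):
    return ActivityTrace(recording_id=rid, rate_hz=rate,
                         activity={nid: np.asarray(x, dtype=float)})


def aligned(x, onsets, rate=5.0, window=(-7.0, 13.0), nid="N", motif="m"):
    return mc.align_to_events(trace_from(x, nid=nid, rate=rate), onsets, nid,
                              motif, window)


class TestAlign:
    def test_window_has_101_samples(self):
        x = np.arange(200.0)
        mat = aligned(x, [15.0])
        assert mat.rows.shape == (1, 101)

    def test_boundary_inclusion_rule(self):
        # 30 s recording at 5/s: onset 10 s included, onset 3 s excluded
        x = np.arange(150.0)
        mat = aligned(x, [10.0, 3.0])
        assert mat.n_instances == 1
        assert mat.n_excluded == 1
        assert mat.onsets_s == [10.0]

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="no usable instances"):
            aligned(np.arange(150.0), [3.0])

    def test_constant_trace_constant_rows(self):
        mat = aligned(np.full(200, 3.3), [15.0, 20.0])
        assert np.ptp(mat.rows) == 0.0

    def test_onset_maps_to_window_time_zero(self):
        x = np.zeros(200)
        x[75] = 1.0  # sample 75 covers [15.0, 15.2)
        mat = aligned(x, [15.0])
        t = mat.window_times()
        assert x[75] == mat.rows[0][np.flatnonzero(t == 0.0)[0]]


class TestAverageResponse:
    def test_constant_rows_flagged(self):
        m1 = aligned(np.full(200, 0.0), [15.0])
        m2 = aligned(np.full(200, 2.0), [15.0])
        curve = mc.average_response([m1, m2])
        assert curve.constant
        np.testing.assert_array_equal(curve.curve, 0.0)

    def test_min_zero_max_one(self, rng):
        mat = aligned(rng.normal(size=300), [20.0, 30.0, 40.0])
        curve = mc.average_response(mat)
        assert curve.curve.min() == 0.0
        assert curve.curve.max() == 1.0

    def test_gain_invariance(self, rng):
        base = rng.normal(size=300)
        c1 = mc.average_response(aligned(base, [20.0, 30.0]))
        c2 = mc.average_response(aligned(5.0 * base + 2.0, [20.0, 30.0]))
        np.testing.assert_allclose(c1.curve, c2.curve, atol=1e-12)

    def test_counts(self):
        m1 = aligned(np.arange(200.0), [15.0, 20.0], nid="N")
        m2 = mc.align_to_events(
            trace_from(np.arange(200.0), rid="t2"), [25.0], "N", "m")
        curve = mc.average_response([m1, m2])
        assert curve.n_instances == 3
        assert curve.n_animals == 2


def interval_ethogram(intervals, duration=60.0, rid="t"):
    return mc.Ethogram(
        recording_id=rid, duration_s=duration,
        intervals={"ventral_contact": [(0.0, duration)],
                   "backward_slide": intervals},
    )


class TestLagCorrelation:
    def _matrix_matching_behavior(self, shift_samples=0):
        """Activity equal to the backward-slide indicator, optionally
        delayed by shift_samples."""
        rate = 5.0
        duration = 60.0
        e = interval_ethogram([(20.0, 30.0)], duration)
        n = int(duration * rate)
        t = (np.arange(n) + 0.5) / rate
        ind = ((t >= 20.0) & (t < 30.0)).astype(float)
        act = np.roll(ind, shift_samples)
        mat = aligned(act, [20.0], rate=rate, motif="backward_slide")
        return mat, e

    def test_identity_gives_lag_zero(self):
        mat, e = self._matrix_matching_behavior(0)
        res = mc.lag_correlation(mat, e, "backward_slide")
        assert res.lag_samples == 0
        assert res.mean_correlation == pytest.approx(1.0)

    def test_activity_delayed_by_one_sample(self):
        # exhaustive over the 11 lags: the delayed copy is found at +1
        mat, e = self._matrix_matching_behavior(1)
        res = mc.lag_correlation(mat, e, "backward_slide")
        assert res.lag_samples == 1
        assert abs(res.mean_correlation) == pytest.approx(1.0)

    def test_negated_behavior_anticorrelated(self):
        rate = 5.0
        e = interval_ethogram([(20.0, 30.0)])
        n = int(60.0 * rate)
        t = (np.arange(n) + 0.5) / rate
        act = -((t >= 20.0) & (t < 30.0)).astype(float)
        mat = aligned(act, [20.0], rate=rate, motif="backward_slide")
        res = mc.lag_correlation(mat, e, "backward_slide")
        assert res.lag_samples == 0
        assert res.mean_correlation == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_point_motif_binarization_single_sample(self):
        e = mc.Ethogram(
            recording_id="t", duration_s=60.0,
            intervals={"ventral_contact": [(0.0, 60.0)]},
            points={"turn_success": [20.0]},
        )
        mat = aligned(np.zeros(300) + np.arange(300) * 0.01, [20.0],
                      motif="turn_success")
        beh = binarize_behavior(e, mat, "turn_success")
        assert beh.sum() == 1.0
        t = mat.window_times()
        assert beh[0][np.flatnonzero(t == 0.0)[0]] == 1.0

    def test_constant_behavior_rows_dropped(self):
        e = interval_ethogram([(0.0, 60.0)])  # covers every window entirely
        mat = aligned(np.arange(300.0), [20.0], motif="backward_slide")
        with pytest.raises(ValueError, match="constant behavior"):
            mc.lag_correlation(mat, e, "backward_slide")

    def test_correlations_bounded(self, rng):
        e = interval_ethogram([(18.0, 25.0), (40.0, 45.0)])
        mat = aligned(rng.normal(size=300), [18.0, 40.0],
                      motif="backward_slide")
        res = mc.lag_correlation(mat, e, "backward_slide")
        assert np.all(np.abs(res.correlations) <= 1.0 + 1e-12)
        assert abs(res.lag_samples) <= 5
        assert len(res.mean_correlation_per_lag) == 11


class TestPeakLatency:
    def test_median_at_exact_peak(self):
        rate = 5.0
        rows = []
        t = -7.0 + np.arange(101) / rate
        for _ in range(5):
            rows.append(np.exp(-((t - 1.2) ** 2)))
        mat = mc.AlignedResponseMatrix(
            neuron_id="N", motif="m", rate_hz=rate, window_s=(-7.0, 13.0),
            rows=np.vstack(rows), onsets_s=[0.0] * 5, recording_ids=["r"] * 5,
        )
        summary = mc.peak_latency(mat)
        assert summary.median_s == pytest.approx(1.2)

    def test_constant_rows_tie_to_window_start(self):
        mat = aligned(np.full(300, 1.0), [20.0])
        summary = mc.peak_latency(mat)
        assert summary.median_s == pytest.approx(-7.0)
        assert summary.constant_rows == 1

    def test_search_range_restricts(self):
        rate = 5.0
        t = -7.0 + np.arange(101) / rate
        row = np.where(t < 0, 5.0, np.exp(-((t - 2.0) ** 2)))
        mat = mc.AlignedResponseMatrix(
            neuron_id="N", motif="m", rate_hz=rate, window_s=(-7.0, 13.0),
            rows=row[None, :], onsets_s=[0.0], recording_ids=["r"],
        )
        summary = mc.peak_latency(mat, search_s=(0.0, 13.0))
        assert summary.median_s == pytest.approx(2.0)

    def test_noisy_kernel_recovery(self):
        import designs

        summary = designs.latency_experiment(1.8, seed=0)
        assert summary.median_s == pytest.approx(1.8, abs=0.2)


class TestCompareLatencies:
    def _summary(self, values, label=""):
        return mc.LatencySummary(
            neuron_id="N", motif="m",
            peak_times_s=np.asarray(values, dtype=float),
            median_s=float(np.median(values)) if len(values) else float("nan"),
            label=label,
        )

    def test_identical_groups(self):
        a = self._summary([1.0, 1.2, 1.4])
        res = mc.compare_latencies(a, a)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_groups_exact_p(self):
        res = mc.compare_latencies(
            self._summary([1.0, 2.0, 3.0]), self._summary([101.0, 102.0, 103.0])
        )
        assert res.p_value == pytest.approx(0.1)

    def test_shifted_groups_significant(self, rng):
        a = self._summary(rng.normal(1.2, 0.2, size=40))
        b = self._summary(rng.normal(1.8, 0.2, size=40))
        res = mc.compare_latencies(a, b)
        assert res.p_value < 0.05

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mc.compare_latencies(self._summary([]), self._summary([1.0]))


class TestConcatenate:
    def test_mismatched_metadata_rejected(self):
        m1 = aligned(np.arange(300.0), [20.0], nid="N", motif="a")
        m2 = aligned(np.arange(300.0), [20.0], nid="N", motif="b")
        with pytest.raises(ValueError, match="not alignable"):
            concatenate_matrices([m1, m2])
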