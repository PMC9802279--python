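import dataclasses
import io as _io

import numpy as np
import pytest

import matecalcium as mc
from matecalcium.ethogram import INTERVAL_EVENTS, POINT_EVENTS
from matecalcium.synthetic import (
    MotionArtifact,
    VolumeGeometry,
    _kernel,
    kernel_peak_time,
    make_tracks,
)


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError, match="turn_success_prob"):
            mc.SimulationConfig(turn_success_prob=1.5)

    def test_bad_duration(self):
        with pytest.raises(ValueError, match="recording_duration_s"):
            mc.SimulationConfig(recording_duration_s=0.0)

    def test_bad_tau(self):
        with pytest.raises(ValueError, match="calcium_decay_tau_s"):
            mc.SimulationConfig(calcium_decay_tau_s=-1.0)

    def test_bad_dwell(self):
        with pytest.raises(ValueError, match="dwell"):
            mc.SimulationConfig(state_dwell_means={"off_contact": 0.0})


class TestSimulateEthogram:
    def test_no_failed_turns_at_probability_one(self):
        cfg = mc.SimulationConfig(recording_duration_s=600.0, turn_success_prob=1.0)
        for seed in range(10):
            e = mc.simulate_ethogram(cfg, seed=seed)
            assert e.count("turn_fail") == 0

    def test_determinism_byte_identical(self, tmp_path, small_config):
        from matecalcium.io import write_ethogram_csv

        paths = []
        for i in (1, 2):
            e = mc.simulate_ethogram(small_config, seed=77)
            p = tmp_path / f"e{i}.csv"
            write_ethogram_csv(e, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_turn_success_rate_monte_carlo(self):
        # pooled over seeds: >= 2000 attempts, empirical rate within +-0.03
        cfg = mc.SimulationConfig(recording_duration_s=300.0, turn_success_prob=0.7)
        ns = nf = 0
        seed = 0
        while ns + nf < 2000:
            e = mc.simulate_ethogram(cfg, seed=seed)
            ns += e.count("turn_success")
            nf += e.count("turn_fail")
            seed += 1
        assert ns / (ns + nf) == pytest.approx(0.7, abs=0.03)

    def test_always_valid(self, small_config):
        for seed in range(25):
            e = mc.simulate_ethogram(small_config, seed=seed)
            assert mc.validate_ethogram(e).ok, mc.validate_ethogram(e).violations

    def test_at_most_one_ejaculation_and_terminal(self):
        cfg = mc.SimulationConfig(
            recording_duration_s=900.0,
            ejaculation_prob_per_vulva_contact=0.8,
            vulva_encounter_rate_per_min=6.0,
        )
        seen = 0
        for seed in range(20):
            e = mc.simulate_ethogram(cfg, seed=seed)
            n = e.count("ejaculation")
            assert n <= 1
            if n == 1:
                seen += 1
                # nothing happens after sperm release
                t_ej = e.points_of("ejaculation")[0]
                assert t_ej == pytest.approx(e.duration_s)
        assert seen > 0

    def test_events_within_recording(self, small_config):
        for seed in range(10):
            e = mc.simulate_ethogram(small_config, seed=seed)
            for ev in INTERVAL_EVENTS:
                for on, off in e.intervals_of(ev):
                    assert 0.0 <= on < off <= e.duration_s
            for ev in POINT_EVENTS:
                for t in e.points_of(ev):
                    assert 0.0 <= t <= e.duration_s

    def test_turn_bookkeeping(self):
        cfg = mc.SimulationConfig(recording_duration_s=600.0, turn_success_prob=0.5)
        e = mc.simulate_ethogram(cfg, seed=5)
        # failed turns coincide with contact losses
        fails = set(e.points_of("turn_fail"))
        losses = set(e.points_of("loss_of_contact"))
        assert fails <= losses


class TestKernel:
    def test_peak_time_analytic_matches_grid(self):
        tau, rise, rate = 1.5, 0.2, 100.0
        k = _kernel(rate, tau, rise)
        grid_peak = (np.argmax(k) + 0.5) / rate
        assert grid_peak == pytest.approx(kernel_peak_time(tau, rise), abs=1.0 / rate)


class TestSimulateTraces:
    def test_constant_channels_without_signal_or_artifact(self):
        cfg = mc.SimulationConfig(
            recording_duration_s=60.0,
            neuron_couplings={"PCA": mc.Coupling("backward_slide", 0.0)},
            channel_noise_sd=0.0,
            motion_artifact=MotionArtifact(0.9, 0.0),
        )
        e = mc.simulate_ethogram(cfg, seed=0)
        raw, _ = mc.simulate_traces(e, cfg, seed=0)
        assert np.ptp(raw.green["PCA"]) == 0.0
        assert np.ptp(raw.red["PCA"]) == 0.0

    def test_backward_coupling_raises_activity_in_motif(self):
        cfg = mc.SimulationConfig(
            recording_duration_s=300.0,
            neuron_couplings={"PCA": mc.Coupling("backward_slide", 1.0, latency_s=0.0)},
            channel_noise_sd=0.0,
            motion_artifact=MotionArtifact(0.9, 0.0),
        )
        e = mc.simulate_ethogram(cfg, seed=3)
        _, truth = mc.simulate_traces(e, cfg, seed=3)
        a = truth.activity["PCA"]
        t = truth.time_s()
        in_motif = np.zeros(len(t), dtype=bool)
        for on, off in e.intervals_of("backward_slide"):
            in_motif |= (t >= on) & (t < off)
        assert in_motif.any()
        assert (a[in_motif] > 0.0).all()

    def test_point_event_peak_at_latency_plus_kernel_peak(self):
        tau, rise = 1.5, 0.2
        latency = 1.2 - kernel_peak_time(tau, rise)
        cfg = mc.SimulationConfig(
            recording_duration_s=120.0,
            neuron_couplings={"PVV": mc.Coupling("turn_success", 1.0, latency_s=latency)},
            calcium_decay_tau_s=tau,
            kernel_rise_s=rise,
            channel_noise_sd=0.0,
            motion_artifact=MotionArtifact(0.9, 0.0),
        )
        e = mc.Ethogram(
            recording_id="t", duration_s=120.0,
            intervals={"ventral_contact": [(0.0, 120.0)]},
            points={"turn_success": [50.0]},
        )
        _, truth = mc.simulate_traces(e, cfg, seed=0)
        a = truth.activity["PVV"]
        peak_t = truth.time_s()[np.argmax(a)]
        assert peak_t - 50.0 == pytest.approx(1.2, abs=0.1)

    def test_common_mode_cancels_exactly(self):
        kwargs = dict(recording_duration_s=60.0, channel_noise_sd=0.0)
        cfg_m = mc.SimulationConfig(motion_artifact=MotionArtifact(0.9, 0.3), **kwargs)
        cfg_0 = mc.SimulationConfig(motion_artifact=MotionArtifact(0.9, 0.0), **kwargs)
        e = mc.simulate_ethogram(cfg_m, seed=4)
        raw_m, _ = mc.simulate_traces(e, cfg_m, seed=4)
        raw_0, _ = mc.simulate_traces(e, cfg_0, seed=4)
        for nid in raw_m.neuron_ids:
            np.testing.assert_allclose(
                raw_m.green[nid] / raw_m.red[nid],
                raw_0.green[nid] / raw_0.red[nid],
                rtol=1e-12,
            )

    def test_no_activation_outside_coupled_motifs(self):
        cfg = mc.SimulationConfig(
            recording_duration_s=300.0,
            spurious_pulse_rate_per_min=0.0,
            neuron_couplings={"PCB": mc.Coupling("vulva_contact", 1.0, latency_s=0.0)},
            channel_noise_sd=0.0,
        )
        e = mc.simulate_ethogram(cfg, seed=6)
        _, truth = mc.simulate_traces(e, cfg, seed=6)
        a = truth.activity["PCB"]
        t = truth.time_s()
        # before the first vulva contact there is no drive at all
        vulva = e.intervals_of("vulva_contact")
        if vulva:
            assert np.all(a[t < vulva[0][0]] == 0.0)

    def test_event_outside_duration_rejected(self, small_config):
        e = mc.Ethogram(
            recording_id="t", duration_s=50.0,
            points={"turn_success": [49.0]},
        )
        e.duration_s = 30.0  # corrupt after construction
        with pytest.raises(ValueError, match="exceeds recording duration"):
            mc.simulate_traces(e, small_config, seed=0)

    def test_spurious_truth_outside_vulva(self):
        cfg = mc.SimulationConfig(
            recording_duration_s=600.0,
            spurious_pulse_rate_per_min=1.0,
            spurious_neurons=("PCB",),
            vulva_encounter_rate_per_min=3.0,
            stop_at_vulva_prob=1.0,
            ejaculation_prob_per_vulva_contact=0.0,
        )
        e = mc.simulate_ethogram(cfg, seed=7)
        _, truth = mc.simulate_traces(e, cfg, seed=7)
        guard = cfg.spurious_guard_margin_s
        for on, off in truth.spurious_intervals["PCB"]:
            for v_on, v_off in e.intervals_of("vulva_contact"):
                assert off + guard <= v_on or on - guard >= v_off

    def test_determinism(self, small_config):
        e = mc.simulate_ethogram(small_config, seed=9)
        r1, t1 = mc.simulate_traces(e, small_config, seed=9)
        r2, t2 = mc.simulate_traces(e, small_config, seed=9)
        for nid in r1.neuron_ids:
            np.testing.assert_array_equal(r1.green[nid], r2.green[nid])
            np.testing.assert_array_equal(t1.activity[nid], t2.activity[nid])


class TestRenderVolumes:
    def _raw(self, n=20, g=200.0, r=100.0):
        return mc.RawTraces(
            recording_id="t", rate_hz=10.0,
            green={"PCA": np.full(n, g)}, red={"PCA": np.full(n, r)},
        )

    def test_round_trip_constant_ratio(self):
        geom = VolumeGeometry()
        raw = self._raw()
        tracks = make_tracks(["PCA"], 20, geom)
        vols = mc.render_volumes(raw, tracks, geom)
        rt = mc.extract_roi_signals(vols, tracks)
        act = mc.compute_activity_trace(rt, window=5)
        np.testing.assert_allclose(act.activity["PCA"], 2.0, rtol=1e-5)

    def test_zero_amplitude_channel_is_offset(self):
        geom = VolumeGeometry()
        raw = mc.RawTraces(
            recording_id="t", rate_hz=10.0,
            green={"PCA": np.full(5, 7.0)}, red={"PCA": np.zeros(5)},
        )
        vols = mc.render_volumes(raw, make_tracks(["PCA"], 5, geom), geom,
                                 camera_offset=0.0)
        assert np.all(vols.red == 0.0)
        vols2 = mc.render_volumes(raw, make_tracks(["PCA"], 5, geom), geom,
                                  camera_offset=7.0)
        np.testing.assert_allclose(vols2.green, 7.0)

    def test_center_outside_grid_names_neuron_and_volume(self):
        geom = VolumeGeometry()
        raw = self._raw(n=3)
        tracks = make_tracks(["PCA"], 3, geom)
        tracks.loc[tracks["volume_index"] == 2, "x_um"] = 1e4
        with pytest.raises(ValueError, match=r"PCA.*volume 2"):
            mc.render_volumes(raw, tracks, geom)

    def test_missing_volume_in_tracks(self):
        geom = VolumeGeometry()
        raw = self._raw(n=4)
        tracks = make_tracks(["PCA"], 3, geom)  # one volume short
        with pytest.raises(ValueError, match="missing volume 3"):
            mc.render_volumes(raw, tracks, geom)
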