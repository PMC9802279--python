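"""Shared simulation designs for recovery/validation tests.

Each "experiment" builds a dataset from the synthetic generator with known
ground truth and runs the package's analysis path on it.
"""

from __future__ import annotations

import numpy as np

import matecalcium as mc
from matecalcium.alignment import concatenate_matrices
from matecalcium.extraction import ActivityTrace
from matecalcium.synthetic import MotionArtifact, kernel_peak_time

KERNEL_TAU_S = 1.5
KERNEL_RISE_S = 0.2


def coupling_experiment(seed: int, gain: float, latency_s: float = 0.6):
    """Pooled-recording lag-correlation experiment.

    Ten 200-s recordings with long backward/forward slide dwells (so
    peri-event windows rarely overlap), one neuron coupled to backward
    sliding with the given gain and latency through a fast kernel.  The
    channel noise is sized so the per-sample ratio noise sd is ~0.2 (gain
    0.6 = 3x noise sd).  Returns the LagCorrelationResult.
    """
    mats, eths = [], {}
    for k in range(10):
        cfg = mc.SimulationConfig(
            recording_duration_s=200.0,
            turn_attempt_prob=0.0,
            turn_success_prob=1.0,
            vulva_encounter_rate_per_min=0.0,
            pause_rate_per_min=0.0,
            state_dwell_means={
                "off_contact": 4.0,
                "backward_slide": 60.0,
                "forward_slide": 40.0,
                "vulva_contact": 6.0,
                "pause_away_from_vulva": 3.0,
            },
            neuron_couplings={
                "PCA": mc.Coupling("backward_slide", gain, latency_s=latency_s)
            },
            calcium_decay_tau_s=0.15,
            kernel_rise_s=0.03,
            channel_noise_sd=14.1,
            motion_artifact=MotionArtifact(0.9, 0.1),
        )
        rid = f"r{k}"
        e = mc.simulate_ethogram(cfg, seed=seed * 100 + k, recording_id=rid)
        raw, _ = mc.simulate_traces(e, cfg, seed=seed * 100 + k)
        act = mc.compute_activity_trace(raw)
        try:
            mats.append(
                mc.align_to_events(
                    act, e.onsets_of("backward_slide"), "PCA", "backward_slide"
                )
            )
        except ValueError:
            continue
        eths[rid] = e
    return mc.lag_correlation(concatenate_matrices(mats), eths, "backward_slide")


def latency_experiment(
    target_peak_s: float, seed: int, n_instances: int = 50, noise_sd: float = 0.1
):
    """Peak-latency recovery from noisy event-locked kernels.

    Point-event (turn) coupling with latency chosen so the analytic kernel
    peak lands at ``target_peak_s`` after the onset.  Rows are the
    ground-truth activity block-meaned to 5 samples/s plus Gaussian noise
    (sd as a fraction of the unit kernel peak).  Returns the
    LatencySummary over >= n_instances pooled instances.
    """
    lat = target_peak_s - kernel_peak_time(KERNEL_TAU_S, KERNEL_RISE_S)
    rng = np.random.default_rng(seed)
    mats, k = [], 0
    while sum(m.n_instances for m in mats) < n_instances and k < 60:
        cfg = mc.SimulationConfig(
            recording_duration_s=400.0,
            turn_attempt_prob=0.6,
            turn_success_prob=1.0,
            vulva_encounter_rate_per_min=0.0,
            pause_rate_per_min=0.0,
            state_dwell_means={
                "off_contact": 4.0,
                "backward_slide": 20.0,
                "forward_slide": 15.0,
                "vulva_contact": 6.0,
                "pause_away_from_vulva": 3.0,
            },
            neuron_couplings={"PVV": mc.Coupling("turn_success", 1.0, latency_s=lat)},
            calcium_decay_tau_s=KERNEL_TAU_S,
            kernel_rise_s=KERNEL_RISE_S,
        )
        rid = f"r{k}"
        e = mc.simulate_ethogram(cfg, seed=seed * 60 + k, recording_id=rid)
        _, truth = mc.simulate_traces(e, cfg, seed=seed * 60 + k)
        a = truth.activity["PVV"]
        n = (len(a) // 2) * 2
        a5 = a[:n].reshape(-1, 2).mean(axis=1)
        a5 = a5 + rng.normal(0.0, noise_sd, size=len(a5))
        act = ActivityTrace(recording_id=rid, rate_hz=5.0, activity={"PVV": a5})
        try:
            mats.append(
                mc.align_to_events(act, e.onsets_of("turn_success"), "PVV", "turn_success")
            )
        except ValueError:
            pass
        k += 1
    return mc.peak_latency(concatenate_matrices(mats))


def detector_experiment(seed: int, spurious_rate_per_min: float, noise_sd: float = 3.0):
    """Spurious-pulse detection against injected ground truth.

    One 300-s recording; PCB is coupled to vulva contact (anchoring the
    min-max normalization) and carries injected 2-s spurious pulses at
    twice the vulva-response drive (so ~2x the 0.5 detection threshold).
    Returns (n_truth, n_detected, n_truth_matched, n_detected_matched).
    """
    cfg = mc.SimulationConfig(
        recording_duration_s=300.0,
        vulva_encounter_rate_per_min=2.0,
        stop_at_vulva_prob=1.0,
        ejaculation_prob_per_vulva_contact=0.0,
        neuron_couplings={"PCB": mc.Coupling("vulva_contact", 1.0)},
        spurious_pulse_rate_per_min=spurious_rate_per_min,
        spurious_neurons=("PCB",),
        spurious_pulse_amplitude=2.0,
        spurious_pulse_duration_s=2.0,
        channel_noise_sd=noise_sd,
        motion_artifact=MotionArtifact(0.9, 0.05),
    )
    e = mc.simulate_ethogram(cfg, seed=seed)
    raw, truth = mc.simulate_traces(e, cfg, seed=seed)
    act = mc.compute_activity_trace(raw)
    call = mc.detect_pulses(act, "PCB", e.intervals_of("vulva_contact"))
    truths = truth.spurious_intervals.get("PCB", [])

    def overlaps(p, t):
        # detection lags the injected boxcar by the kernel rise; allow the
        # calcium decay tail when matching
        return p[0] < t[1] + 1.5 and p[1] > t[0]

    matched_truth = sum(1 for t in truths if any(overlaps(p, t) for p in call.pulses))
    matched_det = sum(1 for p in call.pulses if any(overlaps(p, t) for t in truths))
    return len(truths), len(call.pulses), matched_truth, matched_det


def spurious_cohort_trace(
    rid: str, positive: bool, seed: int, duration_s: float = 120.0, rate_hz: float = 5.0
):
    """Constructed activity trace + vulva intervals for cohort-fraction tests.

    Every male has a vulva-contact response plateau (normalization anchor)
    and low noise; positive males additionally carry two 2-s pulses of
    normalized amplitude ~0.9 away from vulva contact.
    Returns (ActivityTrace, vulva_intervals).
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate_hz)
    t = (np.arange(n) + 0.5) / rate_hz
    vulva = [(60.0, 70.0)]
    x = 1.0 + 0.02 * rng.standard_normal(n)
    x[(t >= 60.0) & (t < 70.0)] += 1.0  # vulva response, sets the range
    if positive:
        for on in (20.0, 90.0):
            x[(t >= on) & (t < on + 2.0)] += 0.9
    return ActivityTrace(recording_id=rid, rate_hz=rate_hz, activity={"PCB": x}), vulva
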