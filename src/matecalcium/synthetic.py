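"""Synthetic mating recordings with ground truth.

Generates motif-structured ethograms (semi-Markov with exponential dwell
times), neural activity coupled to motifs through a calcium-like kernel,
two-channel fluorescence emissions with a shared multiplicative motion
artifact, injected spurious-activation pulses, and optionally rendered
two-channel volumes.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ethogram import Ethogram

DEFAULT_DWELL_MEANS: dict[str, float] = {
    "off_contact": 8.0,
    "backward_slide": 10.0,
    "forward_slide": 8.0,
    "vulva_contact": 6.0,
    "pause_away_from_vulva": 3.0,
}

VULVA_CIRCUIT_NEURONS: tuple[str, ...] = ("PCB", "PCC", "HOA", "HOB", "R2B")


@dataclass(frozen=True)
class Coupling:
    """One neuron's coupling to a driving motif."""

    motif: str
    gain: float
    latency_s: float = 0.0


@dataclass(frozen=True)
class MotionArtifact:
    """Multiplicative log-AR(1) common-mode process shared by both channels."""

    ar_coeff: float = 0.95
    log_sd: float = 0.0  # stationary sd of log m(t)


def default_couplings() -> dict[str, Coupling]:
    c: dict[str, Coupling] = {
        "PCA": Coupling("backward_slide", gain=1.0),
        "PVV": Coupling("turn_success", gain=1.0, latency_s=0.7),
    }
    for nid in VULVA_CIRCUIT_NEURONS:
        c[nid] = Coupling("vulva_contact", gain=1.0)
    return c


@dataclass
class SimulationConfig:
    """Parameters of one simulated recording.

    Dwell times are exponential with the configured means; probabilities are
    per attempt/contact; rates are per minute.  ``seed`` is the default seed
    used when an operation is not given one explicitly.
    """

    recording_duration_s: float = 300.0
    state_dwell_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DWELL_MEANS)
    )
    turn_success_prob: float = 0.8
    vulva_encounter_rate_per_min: float = 2.0
    stop_at_vulva_prob: float = 0.7
    ejaculation_prob_per_vulva_contact: float = 0.1
    pause_rate_per_min: float = 1.0
    turn_attempt_prob: float = 0.5  # at the end of a backward-slide segment
    slide_over_prob: float = 0.1  # at the end of a forward-slide segment
    spurious_pulse_rate_per_min: float = 0.0
    spurious_neurons: tuple[str, ...] = VULVA_CIRCUIT_NEURONS
    spurious_pulse_amplitude: float = 1.0
    spurious_pulse_duration_s: float = 2.0
    spurious_guard_margin_s: float = 4.0
    neuron_couplings: dict[str, Coupling] = field(default_factory=default_couplings)
    calcium_decay_tau_s: float = 1.5
    kernel_rise_s: float = 0.2
    motion_artifact: MotionArtifact = field(default_factory=MotionArtifact)
    channel_noise_sd: float = 0.0
    camera_offset: float = 0.0
    baseline_green: float = 100.0
    baseline_red: float = 100.0
    volume_rate_hz: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("turn_success_prob", "stop_at_vulva_prob",
                     "ejaculation_prob_per_vulva_contact", "turn_attempt_prob",
                     "slide_over_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not self.recording_duration_s > 0:
            raise ValueError("recording_duration_s must be positive")
        for k, v in self.state_dwell_means.items():
            if not v > 0:
                raise ValueError(f"dwell mean for {k!r} must be positive, got {v}")
        for name in ("vulva_encounter_rate_per_min", "pause_rate_per_min",
                     "spurious_pulse_rate_per_min", "channel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.calcium_decay_tau_s > 0:
            raise ValueError("calcium_decay_tau_s must be positive")
        if not 0 < self.kernel_rise_s < self.calcium_decay_tau_s:
            raise ValueError("kernel_rise_s must be in (0, calcium_decay_tau_s)")
        if not 0 <= self.motion_artifact.ar_coeff < 1:
            raise ValueError("motion AR(1) coefficient must be in [0, 1)")
        if self.motion_artifact.log_sd < 0:
            raise ValueError("motion log sd must be >= 0")
        if not self.volume_rate_hz > 0:
            raise ValueError("volume_rate_hz must be positive")


@dataclass
class RawTraces:
    """Per-neuron green/red mean-ROI intensities at the acquisition rate."""

    recording_id: str
    rate_hz: float
    green: dict[str, np.ndarray]
    red: dict[str, np.ndarray]

    @property
    def neuron_ids(self) -> list[str]:
        return sorted(self.green)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.green.values())))

    def time_s(self) -> np.ndarray:
        return (np.arange(self.n_samples) + 0.5) / self.rate_hz


@dataclass
class GroundTruth:
    """Everything injected by the simulator, for downstream scoring."""

    recording_id: str
    rate_hz: float
    activity: dict[str, np.ndarray]  # noiseless a_i(t), baseline 0
    couplings: dict[str, Coupling]
    spurious_intervals: dict[str, list[tuple[float, float]]]
    ethogram: Ethogram

    def time_s(self) -> np.ndarray:
        n = len(next(iter(self.activity.values())))
        return (np.arange(n) + 0.5) / self.rate_hz


# ---------------------------------------------------------------------------
# ethogram generation
# ---------------------------------------------------------------------------


def simulate_ethogram(
    config: SimulationConfig, seed: int | None = None, recording_id: str = "sim"
) -> Ethogram:
    """Semi-Markov mating ethogram.

    Off-contact and ventral-contact alternate.  Within contact, backward and
    forward sliding segments alternate; backward sliding can be interrupted
    by vulva encounters (Poisson, per minute of backward sliding) or pauses;
    each completed backward segment ends in a turn attempt with probability
    ``turn_attempt_prob``, each attempt succeeding with
    ``turn_success_prob``.  A failed turn ends ventral contact.  Ejaculation
    occurs at most once and terminates the recording.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.recording_duration_s
    dwell = config.state_dwell_means
    e = Ethogram(recording_id=recording_id, duration_s=T)

    vulva_rate = config.vulva_encounter_rate_per_min / 60.0
    pause_rate = config.pause_rate_per_min / 60.0

    t = 0.0
    ejaculated = False
    while t < T and not ejaculated:
        t += rng.exponential(dwell["off_contact"])
        if t >= T:
            break
        c0 = t
        direction = "backward_slide"
        in_contact = True
        while in_contact and t < T and not ejaculated:
            seg0 = t
            seg_end = min(seg0 + rng.exponential(dwell[direction]), T)
            if direction == "backward_slide":
                u_v = rng.exponential(1.0 / vulva_rate) if vulva_rate > 0 else math.inf
                u_p = rng.exponential(1.0 / pause_rate) if pause_rate > 0 else math.inf
                u = min(u_v, u_p)
                if seg0 + u < seg_end:
                    # slide interrupted by a vulva encounter or a pause
                    t = seg0 + u
                    if t > seg0:
                        e.intervals["backward_slide"].append((seg0, t))
                    if u_v <= u_p:
                        if rng.random() < config.stop_at_vulva_prob:
                            v0 = t
                            v_end = min(v0 + rng.exponential(dwell["vulva_contact"]), T)
                            if rng.random() < config.ejaculation_prob_per_vulva_contact:
                                e_t = min(v0 + 0.5 * (v_end - v0) + 0.5, T)
                                if e_t > v0:
                                    e.intervals["vulva_contact"].append((v0, e_t))
                                e.points["spicule_insertion"].append(
                                    max(v0, e_t - 0.5)
                                )
                                e.points["ejaculation"].append(e_t)
                                t = e_t
                                ejaculated = True
                                in_contact = False
                            else:
                                if v_end > v0:
                                    e.intervals["vulva_contact"].append((v0, v_end))
                                t = v_end
                        else:
                            e.points["vulva_pass"].append(t)
                    else:
                        p0 = t
                        p_end = min(
                            p0 + rng.exponential(dwell["pause_away_from_vulva"]), T
                        )
                        if p_end > p0:
                            e.intervals["pause_away_from_vulva"].append((p0, p_end))
                        t = p_end
                    continue  # resume backward sliding in a fresh segment
            if seg_end > seg0:
                e.intervals[direction].append((seg0, seg_end))
            t = seg_end
            if t >= T:
                break
            if direction == "backward_slide":
                if rng.random() < config.turn_attempt_prob:
                    if rng.random() < config.turn_success_prob:
                        e.points["turn_success"].append(t)
                    else:
                        e.points["turn_fail"].append(t)
                        e.points["loss_of_contact"].append(t)
                        in_contact = False
                else:
                    direction = "forward_slide"
            else:
                if rng.random() < config.slide_over_prob:
                    e.points["slide_over"].append(t)
                    e.points["loss_of_contact"].append(t)
                    in_contact = False
                else:
                    direction = "backward_slide"
        contact_end = min(t, T)
        if contact_end > c0:
            e.intervals["ventral_contact"].append((c0, contact_end))
    if ejaculated:
        # sperm release ends the recording
        e.duration_s = t
    return e


# ---------------------------------------------------------------------------
# kernel and traces
# ---------------------------------------------------------------------------


def kernel_peak_time(tau_s: float, rise_s: float) -> float:
    """Analytic argmax of the difference-of-exponentials kernel."""
    return tau_s * rise_s / (tau_s - rise_s) * math.log(tau_s / rise_s)


def _kernel(rate_hz: float, tau_s: float, rise_s: float) -> np.ndarray:
    """Causal kernel sampled at sample midpoints, cut at 8 tau."""
    n = max(int(math.ceil(8.0 * tau_s * rate_hz)), 2)
    th = (np.arange(n) + 0.5) / rate_hz
    k = np.exp(-th / tau_s) - np.exp(-th / rise_s)
    return k


def _drive_from_intervals(
    ind: np.ndarray, kernel: np.ndarray
) -> np.ndarray:
    """Interval drive: indicator convolved with the unit-area kernel."""
    ka = kernel / kernel.sum()
    return np.convolve(ind, ka)[: len(ind)]


def _drive_from_points(
    times: list[float], n: int, rate_hz: float, kernel: np.ndarray
) -> np.ndarray:
    """Point drive: unit-peak kernel stamped at each event time."""
    kp = kernel / kernel.max()
    out = np.zeros(n)
    for t0 in times:
        i0 = int(math.floor(t0 * rate_hz))
        m = min(len(kp), n - i0)
        if m > 0 and i0 >= 0:
            out[i0 : i0 + m] += kp[:m]
    return out


def _motion_process(
    n: int, artifact: MotionArtifact, rng: np.random.Generator
) -> np.ndarray:
    if artifact.log_sd == 0:
        return np.ones(n)
    phi = artifact.ar_coeff
    innov_sd = artifact.log_sd * math.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, artifact.log_sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return np.exp(x)


def _inject_spurious(
    e: Ethogram,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Draw spurious-pulse intervals outside (dilated) vulva contact."""
    T = e.duration_s
    dur = config.spurious_pulse_duration_s
    guard = config.spurious_guard_margin_s
    lam = config.spurious_pulse_rate_per_min / 60.0
    n_pulses = rng.poisson(lam * T)
    vulva = e.intervals_of("vulva_contact")
    pulses: list[tuple[float, float]] = []
    for _ in range(n_pulses):
        for _ in range(200):  # rejection sampling
            on = rng.uniform(1.0, max(T - dur - 1.0, 1.0 + 1e-9))
            off = on + dur
            clear = all(
                off + guard <= v_on or on - guard >= v_off for v_on, v_off in vulva
            )
            if clear and all(off <= p_on or on >= p_off for p_on, p_off in pulses):
                pulses.append((on, off))
                break
    return sorted(pulses)


def simulate_traces(
    ethogram: Ethogram,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[RawTraces, GroundTruth]:
    """Coupled activity and two-channel emissions for one ethogram.

    Noiseless activity is ``a_i(t) = sum_events gain * k(t - t_event -
    latency)`` with k the difference-of-exponentials kernel (unit peak for
    point events, unit area for boxcar-driven interval events).  Emissions::

        G_i(t) = c_g * (1 + a_i(t)) * m(t) + offset + noise
        R_i(t) = c_r * m(t)            + offset + noise

    with m(t) the positive common-mode motion artifact shared by both
    channels of a neuron.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.volume_rate_hz
    T = ethogram.duration_s
    n = int(round(T * rate))
    tmid = (np.arange(n) + 0.5) / rate
    kern = _kernel(rate, config.calcium_decay_tau_s, config.kernel_rise_s)

    from .ethogram import INTERVAL_EVENTS, POINT_EVENTS

    for ev in INTERVAL_EVENTS:
        for on, off in ethogram.intervals_of(ev):
            if off > T + 1e-9:
                raise ValueError(
                    f"{ev} interval [{on}, {off}] exceeds recording duration {T}"
                )
    for ev in POINT_EVENTS:
        for t0 in ethogram.points_of(ev):
            if t0 > T + 1e-9:
                raise ValueError(f"{ev} at {t0} s exceeds recording duration {T}")

    spurious: dict[str, list[tuple[float, float]]] = {}
    if config.spurious_pulse_rate_per_min > 0:
        for nid in config.spurious_neurons:
            spurious[nid] = _inject_spurious(ethogram, config, rng)

    activity: dict[str, np.ndarray] = {}
    green: dict[str, np.ndarray] = {}
    red: dict[str, np.ndarray] = {}
    for nid in sorted(config.neuron_couplings):
        coup = config.neuron_couplings[nid]
        a = np.zeros(n)
        if coup.gain != 0.0:
            if coup.motif in INTERVAL_EVENTS:
                ind = np.zeros(n)
                for on, off in ethogram.intervals_of(coup.motif):
                    lo = np.searchsorted(tmid, on + coup.latency_s)
                    hi = np.searchsorted(tmid, off + coup.latency_s)
                    ind[lo:hi] = 1.0
                a += coup.gain * _drive_from_intervals(ind, kern)
            elif coup.motif in POINT_EVENTS:
                times = [t0 + coup.latency_s for t0 in ethogram.points_of(coup.motif)]
                a += coup.gain * _drive_from_points(times, n, rate, kern)
            else:
                raise ValueError(f"unknown driving motif {coup.motif!r} for {nid}")
        for on, off in spurious.get(nid, []):
            ind = ((tmid >= on) & (tmid < off)).astype(float)
            a += config.spurious_pulse_amplitude * _drive_from_intervals(ind, kern)
        activity[nid] = a

        m = _motion_process(n, config.motion_artifact, rng)
        noise_g = (
            rng.normal(0.0, config.channel_noise_sd, size=n)
            if config.channel_noise_sd > 0
            else 0.0
        )
        noise_r = (
            rng.normal(0.0, config.channel_noise_sd, size=n)
            if config.channel_noise_sd > 0
            else 0.0
        )
        green[nid] = config.baseline_green * (1.0 + a) * m + config.camera_offset + noise_g
        red[nid] = config.baseline_red * m + config.camera_offset + noise_r

    raw = RawTraces(
        recording_id=ethogram.recording_id, rate_hz=rate, green=green, red=red
    )
    truth = GroundTruth(
        recording_id=ethogram.recording_id,
        rate_hz=rate,
        activity=activity,
        couplings=dict(config.neuron_couplings),
        spurious_intervals=spurious,
        ethogram=ethogram,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# volume rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid of the rendered recording.

    Acquisition constants (0.45 um lateral pixels, 1.75 um slice spacing,
    10 volumes/s) at a reduced desk-scale lateral extent.  Voxel index i
    lies at coordinate ``i * spacing`` um along each axis.
    """

    n_slices: int = 10
    height_px: int = 32
    width_px: int = 64
    pixel_size_um: float = 0.45
    slice_spacing_um: float = 1.75
    volume_rate_hz: float = 10.0
    blob_sigma_um: tuple[float, float, float] = (0.7, 0.7, 1.3)  # x, y, z
    jitter_sd_um: float = 0.0


def make_tracks(
    neuron_ids: list[str], n_volumes: int, geometry: VolumeGeometry
) -> pd.DataFrame:
    """Static nucleus tracks spread over the grid interior."""
    g = geometry
    xs = np.linspace(0.2, 0.8, max(len(neuron_ids), 2))[: len(neuron_ids)]
    rows = []
    for nid, fx in zip(sorted(neuron_ids), xs):
        x = fx * (g.width_px - 1) * g.pixel_size_um
        y = 0.5 * (g.height_px - 1) * g.pixel_size_um
        z = 0.5 * (g.n_slices - 1) * g.slice_spacing_um
        for v in range(n_volumes):
            rows.append((v, nid, x, y, z))
    return pd.DataFrame(
        rows, columns=["volume_index", "neuron_id", "x_um", "y_um", "z_um"]
    )


def render_volumes(
    raw: RawTraces,
    tracks: pd.DataFrame,
    geometry: VolumeGeometry | None = None,
    seed: int | None = None,
    camera_offset: float = 0.0,
):
    """Render each nucleus as an anisotropic 3D Gaussian blob.

    Blob amplitude is the channel signal minus ``camera_offset``; the offset
    is added back to every voxel so a zero-amplitude channel renders as a
    uniform ``camera_offset`` image.  Returns a
    :class:`~matecalcium.extraction.VolumeSeries`.
    """
    from .extraction import VolumeSeries

    g = geometry or VolumeGeometry()
    rng = np.random.default_rng(0 if seed is None else seed)
    n_vol = raw.n_samples
    shape = (n_vol, g.n_slices, g.height_px, g.width_px)
    vol_g = np.full(shape, camera_offset, dtype=np.float64)
    vol_r = np.full(shape, camera_offset, dtype=np.float64)

    by_neuron = {}
    for nid, grp in tracks.groupby("neuron_id"):
        grp = grp.sort_values("volume_index")
        by_neuron[str(nid)] = (
            grp["volume_index"].to_numpy(),
            grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        )
    for nid in raw.neuron_ids:
        if nid not in by_neuron:
            raise ValueError(f"tracks missing neuron {nid!r}")
        vol_idx, xyz = by_neuron[nid]
        missing = set(range(n_vol)) - set(vol_idx.tolist())
        if missing:
            raise ValueError(
                f"tracks for neuron {nid!r} missing volume {min(missing)}"
            )
        pos_by_vol = dict(zip(vol_idx.tolist(), xyz))
        sx, sy, sz = g.blob_sigma_um
        for v in range(n_vol):
            x, y, z = pos_by_vol[v]
            if g.jitter_sd_um > 0:
                x += rng.normal(0, g.jitter_sd_um)
                y += rng.normal(0, g.jitter_sd_um)
                z += rng.normal(0, g.jitter_sd_um)
            px, py = x / g.pixel_size_um, y / g.pixel_size_um
            pz = z / g.slice_spacing_um
            if not (
                0 <= px <= g.width_px - 1
                and 0 <= py <= g.height_px - 1
                and 0 <= pz <= g.n_slices - 1
            ):
                raise ValueError(
                    f"blob center for neuron {nid!r} at volume {v} lies outside "
                    f"the grid (x={x:.2f}, y={y:.2f}, z={z:.2f} um)"
                )
            rx = int(math.ceil(3 * sx / g.pixel_size_um))
            ry = int(math.ceil(3 * sy / g.pixel_size_um))
            rz = int(math.ceil(3 * sz / g.slice_spacing_um))
            ix0, ix1 = max(0, int(px) - rx), min(g.width_px, int(px) + rx + 2)
            iy0, iy1 = max(0, int(py) - ry), min(g.height_px, int(py) + ry + 2)
            iz0, iz1 = max(0, int(pz) - rz), min(g.n_slices, int(pz) + rz + 2)
            dx = np.arange(ix0, ix1) * g.pixel_size_um - x
            dy = np.arange(iy0, iy1) * g.pixel_size_um - y
            dz = np.arange(iz0, iz1) * g.slice_spacing_um - z
            blob = np.exp(
                -(
                    dz[:, None, None] ** 2 / (2 * sz**2)
                    + dy[None, :, None] ** 2 / (2 * sy**2)
                    + dx[None, None, :] ** 2 / (2 * sx**2)
                )
            )
            amp_g = raw.green[nid][v] - camera_offset
            amp_r = raw.red[nid][v] - camera_offset
            vol_g[v, iz0:iz1, iy0:iy1, ix0:ix1] += amp_g * blob
            vol_r[v, iz0:iz1, iy0:iy1, ix0:ix1] += amp_r * blob

    return VolumeSeries(
        green=vol_g.astype(np.float32),
        red=vol_r.astype(np.float32),
        pixel_size_um=g.pixel_size_um,
        slice_spacing_um=g.slice_spacing_um,
        volume_rate_hz=g.volume_rate_hz,
    )
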