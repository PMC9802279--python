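"""Screening for spurious activation of the vulva-detecting circuit.

Detects supra-threshold pulses of normalized activity occurring away from
(dilated) vulva-contact intervals, classifies males as spurious-positive if
any designated circuit neuron pulses, and reports per-genotype fractions
with floored integer percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .extraction import ActivityTrace

logger = logging.getLogger(__name__)

DEFAULT_CIRCUIT_NEURONS: frozenset[str] = frozenset(
    {"PCB", "PCC", "HOA", "HOB", "R2B"}
)


@dataclass(frozen=True)
class DetectorParams:
    threshold: float = 0.5  # of the per-recording min-max normalized range
    min_duration_s: float = 1.0
    guard_s: float = 2.0  # dilation of vulva-contact intervals

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.min_duration_s <= 0 or self.guard_s < 0:
            raise ValueError("min_duration_s must be > 0 and guard_s >= 0")


@dataclass
class SpuriousCall:
    """Detected off-vulva activation pulses for one neuron of one recording."""

    recording_id: str
    neuron_id: str
    pulses: list[tuple[float, float]]
    peaks: list[float]  # peak normalized amplitude per pulse
    params: DetectorParams = field(default_factory=DetectorParams)

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)


def _normalize(x: np.ndarray) -> np.ndarray | None:
    span = np.ptp(x)
    if span == 0:
        return None
    return (x - x.min()) / span


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open sample index pairs."""
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def detect_pulses(
    trace: ActivityTrace,
    neuron_id: str,
    vulva_intervals: list[tuple[float, float]],
    params: DetectorParams = DetectorParams(),
) -> SpuriousCall:
    """Supra-threshold pulses outside dilated vulva-contact intervals.

    The trace is min-max normalized per recording; pulses are maximal runs
    above ``threshold`` lasting at least ``min_duration_s``, intersected
    with the complement of vulva intervals dilated by ``+-guard_s``.  Runs
    partially overlapping the dilated intervals are truncated and kept only
    if the remainder still meets the minimum duration.
    """
    x = trace.activity[neuron_id]
    rate = trace.rate_hz
    norm = _normalize(x)
    if norm is None:
        logger.warning(
            "detect_pulses: constant trace for %s/%s; normalization degenerate",
            trace.recording_id,
            neuron_id,
        )
        return SpuriousCall(trace.recording_id, neuron_id, [], [], params)
    dilated = [
        (on - params.guard_s, off + params.guard_s) for on, off in vulva_intervals
    ]
    min_samples = int(math.ceil(params.min_duration_s * rate))
    pulses: list[tuple[float, float]] = []
    peaks: list[float] = []
    for i0, i1 in _runs_above(norm > params.threshold):
        # clip the run against every dilated vulva interval
        segments = [(i0 / rate, i1 / rate)]
        for v_on, v_off in dilated:
            nxt = []
            for s_on, s_off in segments:
                if s_off <= v_on or s_on >= v_off:
                    nxt.append((s_on, s_off))
                    continue
                if s_on < v_on:
                    nxt.append((s_on, v_on))
                if s_off > v_off:
                    nxt.append((v_off, s_off))
            segments = nxt
        for s_on, s_off in segments:
            j0 = int(round(s_on * rate))
            j1 = int(round(s_off * rate))
            if j1 - j0 >= min_samples:
                pulses.append((s_on, s_off))
                peaks.append(float(norm[j0:j1].max()))
    return SpuriousCall(trace.recording_id, neuron_id, pulses, peaks, params)


def classify_male(
    calls: list[SpuriousCall],
    circuit_neurons: frozenset[str] | set[str] = DEFAULT_CIRCUIT_NEURONS,
) -> bool:
    """True iff any designated circuit neuron has at least one pulse."""
    return any(c.n_pulses >= 1 for c in calls if c.neuron_id in circuit_neurons)


def cohort_spurious_fraction(labels: list[bool]) -> tuple[int, int, int]:
    """(n_positive, n_total, floored integer percent)."""
    if not labels:
        raise ValueError("empty cohort")
    n_pos = sum(bool(x) for x in labels)
    n_total = len(labels)
    return n_pos, n_total, math.floor(100 * n_pos / n_total)
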