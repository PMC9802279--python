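"""Ethogram data model and validation.

An ethogram is the timestamped inventory of behavioral events scored for one
male recording.  Events are either intervals (onset/offset pairs, half-open
``[onset, offset)``) or instantaneous points.  The controlled vocabulary
mirrors the events tabulated during manual scoring of mating recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

INTERVAL_EVENTS: tuple[str, ...] = (
    "ventral_contact",
    "vulva_contact",
    "pause_away_from_vulva",
    "backward_slide",
    "forward_slide",
)

POINT_EVENTS: tuple[str, ...] = (
    "turn_success",
    "turn_fail",
    "slide_over",
    "loss_of_contact",
    "vulva_pass",
    "spicule_insertion",
    "ejaculation",
)

EVENT_VOCABULARY: tuple[str, ...] = INTERVAL_EVENTS + POINT_EVENTS


class EthogramError(ValueError):
    """Raised for malformed or inconsistent ethograms."""


@dataclass
class Ethogram:
    """Behavioral events of one recording.

    Parameters
    ----------
    recording_id
        Identifier of the recording the events belong to.
    duration_s
        Recording duration in seconds; all events must fall in
        ``[0, duration_s]``.
    intervals
        Mapping from interval event type to a list of ``(onset, offset)``
        pairs in seconds.
    points
        Mapping from point event type to a list of event times in seconds.
    """

    recording_id: str
    duration_s: float
    intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    points: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ev in self.intervals:
            if ev not in INTERVAL_EVENTS:
                raise EthogramError(f"unknown interval event type {ev!r}")
        for ev in self.points:
            if ev not in POINT_EVENTS:
                raise EthogramError(f"unknown point event type {ev!r}")
        for ev in INTERVAL_EVENTS:
            self.intervals.setdefault(ev, [])
        for ev in POINT_EVENTS:
            self.points.setdefault(ev, [])

    # -- accessors ---------------------------------------------------------

    def intervals_of(self, event_type: str) -> list[tuple[float, float]]:
        if event_type not in INTERVAL_EVENTS:
            raise EthogramError(f"{event_type!r} is not an interval event type")
        return sorted(self.intervals[event_type])

    def points_of(self, event_type: str) -> list[float]:
        if event_type not in POINT_EVENTS:
            raise EthogramError(f"{event_type!r} is not a point event type")
        return sorted(self.points[event_type])

    def onsets_of(self, event_type: str) -> list[float]:
        """Onset times of an event type (interval onsets or point times)."""
        if event_type in INTERVAL_EVENTS:
            return [on for on, _ in self.intervals_of(event_type)]
        return self.points_of(event_type)

    def total_duration_of(self, event_type: str) -> float:
        """Summed duration in seconds of all intervals of one type."""
        return float(sum(off - on for on, off in self.intervals_of(event_type)))

    def count(self, event_type: str) -> int:
        if event_type in INTERVAL_EVENTS:
            return len(self.intervals[event_type])
        return len(self.points[event_type])

    # -- tabular form ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-form event table (one row per event, sorted by onset)."""
        rows = []
        for ev in INTERVAL_EVENTS:
            for on, off in self.intervals[ev]:
                rows.append((self.recording_id, ev, float(on), float(off)))
        for ev in POINT_EVENTS:
            for t in self.points[ev]:
                rows.append((self.recording_id, ev, float(t), None))
        rows.sort(key=lambda r: (r[2], r[1]))
        return pd.DataFrame(
            rows, columns=["recording_id", "event_type", "onset_s", "offset_s"]
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, duration_s: float, recording_id: str | None = None
    ) -> "Ethogram":
        if recording_id is None:
            ids = frame["recording_id"].unique()
            if len(ids) != 1:
                raise EthogramError(
                    f"frame contains {len(ids)} recording ids; pass recording_id"
                )
            recording_id = str(ids[0])
        e = cls(recording_id=recording_id, duration_s=float(duration_s))
        for _, row in frame.iterrows():
            ev = str(row["event_type"])
            if ev in INTERVAL_EVENTS:
                e.intervals[ev].append((float(row["onset_s"]), float(row["offset_s"])))
            elif ev in POINT_EVENTS:
                e.points[ev].append(float(row["onset_s"]))
            else:
                raise EthogramError(
                    f"unknown event_type {ev!r}; valid types: "
                    + ", ".join(EVENT_VOCABULARY)
                )
        return e


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_ethogram`."""

    recording_id: str
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _contained(inner: tuple[float, float], outers: list[tuple[float, float]]) -> bool:
    return any(on <= inner[0] and inner[1] <= off for on, off in outers)


def validate_ethogram(e: Ethogram) -> ValidationReport:
    """Check all ethogram invariants and itemize violations.

    Checked invariants: interval bounds ``0 <= onset < offset <= duration``;
    same-type intervals non-overlapping; vulva-contact intervals nested inside
    ventral-contact intervals; at most one ejaculation; point events inside
    ``[0, duration]``.
    """
    v: list[str] = []
    if not e.duration_s > 0:
        v.append(f"duration must be positive, got {e.duration_s}")
    for ev in INTERVAL_EVENTS:
        ivs = e.intervals_of(ev)
        for on, off in ivs:
            if not (0.0 <= on < off <= e.duration_s):
                v.append(
                    f"{ev} interval [{on}, {off}] violates "
                    f"0 <= onset < offset <= {e.duration_s}"
                )
        for a, b in zip(ivs, ivs[1:]):
            if _overlaps(a, b):
                v.append(f"{ev} intervals {a} and {b} overlap")
    ventral = e.intervals_of("ventral_contact")
    for iv in e.intervals_of("vulva_contact"):
        if not _contained(iv, ventral):
            v.append(f"vulva_contact {iv} outside ventral contact")
    for ev in POINT_EVENTS:
        for t in e.points_of(ev):
            if not (0.0 <= t <= e.duration_s):
                v.append(f"{ev} at {t} s outside [0, {e.duration_s}]")
    n_ej = e.count("ejaculation")
    if n_ej > 1:
        v.append(f"{n_ej} ejaculation events; at most one allowed")
    return ValidationReport(recording_id=e.recording_id, violations=v)
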