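"""Readers and writers for the text/HDF5 interchange formats.

All CSVs are UTF-8 with "." decimal separator; timestamps round-trip
losslessly (floats are written with ``repr``).  JSON results carry a
``schema_version`` field and, when produced by the pipeline, the manifest
hash.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ethogram import (
    EVENT_VOCABULARY,
    INTERVAL_EVENTS,
    POINT_EVENTS,
    Ethogram,
    EthogramError,
)
from .extraction import ActivityTrace, VolumeSeries
from .synthetic import RawTraces

SCHEMA_VERSION = "1"
_ETHOGRAM_COLUMNS = ["recording_id", "event_type", "onset_s", "offset_s"]


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


# ---------------------------------------------------------------------------
# ethograms
# ---------------------------------------------------------------------------


def write_ethogram_csv(e: Ethogram, path: str | Path) -> None:
    path = Path(path)
    frame = e.to_frame()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(f"# recording_duration_s={_fmt(e.duration_s)}\n")
        w = csv.writer(fh)
        w.writerow(_ETHOGRAM_COLUMNS)
        for _, row in frame.iterrows():
            w.writerow(
                [
                    row["recording_id"],
                    row["event_type"],
                    _fmt(row["onset_s"]),
                    _fmt(row["offset_s"]) if pd.notna(row["offset_s"]) else "",
                ]
            )


def read_ethogram_csv(path: str | Path) -> Ethogram:
    path = Path(path)
    duration: float | None = None
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "recording_duration_s":
                    duration = float(val)
                elif key == "schema_version" and val != SCHEMA_VERSION:
                    raise EthogramError(
                        f"{path}: schema version {val!r} != {SCHEMA_VERSION!r}"
                    )
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = fields
                if header != _ETHOGRAM_COLUMNS:
                    raise EthogramError(
                        f"{path}:{lineno}: expected columns {_ETHOGRAM_COLUMNS}, "
                        f"got {header}"
                    )
                continue
            rows.append((lineno, fields))
    if header is None:
        raise EthogramError(f"{path}: no header row found")

    rec_ids = {r[1][0] for r in rows}
    if len(rec_ids) > 1:
        raise EthogramError(f"{path}: multiple recording ids {sorted(rec_ids)}")
    recording_id = rows[0][1][0] if rows else path.stem

    if duration is None:
        # fall back to the latest timestamp present
        times = [float(f[3] or f[2]) for _, f in rows]
        duration = max(times) if times else 0.0

    e = Ethogram(recording_id=recording_id, duration_s=duration)
    for lineno, f in rows:
        if len(f) != 4:
            raise EthogramError(f"{path}:{lineno}: expected 4 fields, got {len(f)}")
        ev = f[1]
        if ev not in EVENT_VOCABULARY:
            raise EthogramError(
                f"{path}:{lineno}: unknown event_type {ev!r}; valid types: "
                + ", ".join(EVENT_VOCABULARY)
            )
        try:
            onset = float(f[2])
            offset = float(f[3]) if f[3] != "" else None
        except ValueError as exc:
            raise EthogramError(f"{path}:{lineno}: malformed timestamp: {exc}") from exc
        if ev in INTERVAL_EVENTS:
            if offset is None:
                raise EthogramError(
                    f"{path}:{lineno}: interval event {ev!r} requires an offset"
                )
            e.intervals[ev].append((onset, offset))
        else:
            if offset is not None:
                raise EthogramError(
                    f"{path}:{lineno}: point event {ev!r} must have an empty offset"
                )
            e.points[ev].append(onset)
    return e


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_traces_csv(
    raw: RawTraces | None,
    path: str | Path,
    activity: ActivityTrace | None = None,
) -> None:
    """Long-form trace table: recording_id, neuron_id, time_s, green, red
    and/or activity (raw and activity tables use their own sampling grids,
    so pass one or the other)."""
    if (raw is None) == (activity is None):
        raise ValueError("pass exactly one of raw or activity")
    src = raw if raw is not None else activity
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(f"# rate_hz={_fmt(src.rate_hz)}\n")
        w = csv.writer(fh)
        if raw is not None:
            w.writerow(["recording_id", "neuron_id", "time_s", "green", "red"])
            t = raw.time_s()
            for nid in raw.neuron_ids:
                for i in range(raw.n_samples):
                    w.writerow(
                        [raw.recording_id, nid, _fmt(t[i]),
                         _fmt(raw.green[nid][i]), _fmt(raw.red[nid][i])]
                    )
        else:
            w.writerow(["recording_id", "neuron_id", "time_s", "activity"])
            t = activity.time_s()
            for nid in activity.neuron_ids:
                for i in range(activity.n_samples):
                    w.writerow(
                        [activity.recording_id, nid, _fmt(t[i]),
                         _fmt(activity.activity[nid][i])]
                    )


def read_traces_csv(path: str | Path) -> RawTraces | ActivityTrace:
    rate = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
                if key == "rate_hz":
                    rate = float(val)
            else:
                break
    if rate is None:
        raise ValueError(f"{path}: missing '# rate_hz=' header")
    df = pd.read_csv(path, comment="#")
    rid = str(df["recording_id"].iloc[0])
    if "green" in df.columns:
        green = {str(n): g["green"].to_numpy() for n, g in df.groupby("neuron_id")}
        red = {str(n): g["red"].to_numpy() for n, g in df.groupby("neuron_id")}
        return RawTraces(recording_id=rid, rate_hz=rate, green=green, red=red)
    act = {str(n): g["activity"].to_numpy() for n, g in df.groupby("neuron_id")}
    return ActivityTrace(recording_id=rid, rate_hz=rate, activity=act)


# ---------------------------------------------------------------------------
# volumes and tracks
# ---------------------------------------------------------------------------


def write_volumes_h5(volumes: VolumeSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("green", data=volumes.green)
        f.create_dataset("red", data=volumes.red)
        f.attrs["pixel_size_um"] = volumes.pixel_size_um
        f.attrs["slice_spacing_um"] = volumes.slice_spacing_um
        f.attrs["volume_rate_hz"] = volumes.volume_rate_hz
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_volumes_h5(path: str | Path) -> VolumeSeries:
    with h5py.File(path, "r") as f:
        return VolumeSeries(
            green=f["green"][...],
            red=f["red"][...],
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            slice_spacing_um=float(f.attrs["slice_spacing_um"]),
            volume_rate_hz=float(f.attrs["volume_rate_hz"]),
        )


def write_volumes_tiff(volumes: VolumeSeries, green_path, red_path) -> None:
    """One multi-page TIFF per channel, pages ordered (volume, slice)."""
    import tifffile

    meta = {
        "pixel_size_um": volumes.pixel_size_um,
        "slice_spacing_um": volumes.slice_spacing_um,
        "volume_rate_hz": volumes.volume_rate_hz,
        "n_slices": volumes.green.shape[1],
    }
    for path, arr in ((green_path, volumes.green), (red_path, volumes.red)):
        tifffile.imwrite(path, arr.reshape(-1, *arr.shape[2:]), metadata=meta)


def write_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks.to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"volume_index", "neuron_id", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tracks CSV missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_results_json(
    results: dict, path: str | Path, manifest_hash: str | None = None
) -> None:
    payload = {"schema_version": SCHEMA_VERSION}
    if manifest_hash is not None:
        payload["manifest_hash"] = manifest_hash
    payload.update(_jsonable(results))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
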