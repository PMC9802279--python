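"""Ratiometric activity-trace extraction from tracked two-channel volumes.

Pipeline: mean-ROI channel signals at the acquisition rate, block-mean
downsampling to the analysis rate, offset-subtracted green/red ratio, then
Savitzky-Golay smoothing of the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import RawTraces

logger = logging.getLogger(__name__)

DEFAULT_ROI_UM: tuple[float, float, float] = (2.25, 2.25, 3.5)
_TIE_EPS = 1e-9  # voxel centers exactly on the ROI face are included


@dataclass
class VolumeSeries:
    """Two-channel volumetric recording with acquisition geometry."""

    green: np.ndarray  # (volume, slice, row, column)
    red: np.ndarray
    pixel_size_um: float
    slice_spacing_um: float
    volume_rate_hz: float

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError(
                f"channel shapes differ: {self.green.shape} vs {self.red.shape}"
            )
        if self.green.ndim != 4:
            raise ValueError("volumes must be 4D (volume, slice, row, column)")
        if not self.volume_rate_hz > 0:
            raise ValueError("volume_rate_hz must be positive")

    @property
    def n_volumes(self) -> int:
        return self.green.shape[0]


@dataclass
class ActivityTrace:
    """Per-neuron ratiometric activity at the analysis rate."""

    recording_id: str
    rate_hz: float
    activity: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    @property
    def neuron_ids(self) -> list[str]:
        return sorted(self.activity)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.activity.values())))

    def time_s(self) -> np.ndarray:
        return (np.arange(self.n_samples) + 0.5) / self.rate_hz


def _axis_range(center_um: float, half_um: float, spacing_um: float, n: int):
    """Index range of voxels whose centers fall within +-half_um of center."""
    lo = int(np.ceil((center_um - half_um - _TIE_EPS) / spacing_um))
    hi = int(np.floor((center_um + half_um + _TIE_EPS) / spacing_um))
    clipped = lo < 0 or hi > n - 1
    return max(lo, 0), min(hi, n - 1), clipped


def extract_roi_signals(
    volumes: VolumeSeries,
    tracks: pd.DataFrame,
    roi_um: tuple[float, float, float] = DEFAULT_ROI_UM,
    recording_id: str = "rec",
) -> RawTraces:
    """Mean intensity per channel over an axis-aligned ROI box per neuron.

    The box collects voxels whose centers lie within ``roi_um / 2`` of the
    nucleus center along each axis (boundary ties included).  Boxes clipped
    at the image border are used as-is, with a logged warning.
    """
    hx, hy, hz = roi_um[0] / 2.0, roi_um[1] / 2.0, roi_um[2] / 2.0
    n_vol = volumes.n_volumes
    _, n_z, n_y, n_x = volumes.green.shape
    green: dict[str, np.ndarray] = {}
    red: dict[str, np.ndarray] = {}
    clipped_any = False
    for nid, grp in tracks.groupby("neuron_id"):
        grp = grp.sort_values("volume_index")
        pos = dict(
            zip(
                grp["volume_index"].tolist(),
                grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            )
        )
        g = np.empty(n_vol)
        r = np.empty(n_vol)
        for v in range(n_vol):
            if v not in pos:
                raise ValueError(f"neuron {nid!r} has no track at volume {v}")
            x, y, z = pos[v]
            ix0, ix1, cx = _axis_range(x, hx, volumes.pixel_size_um, n_x)
            iy0, iy1, cy = _axis_range(y, hy, volumes.pixel_size_um, n_y)
            iz0, iz1, cz = _axis_range(z, hz, volumes.slice_spacing_um, n_z)
            clipped_any = clipped_any or cx or cy or cz
            box = (slice(iz0, iz1 + 1), slice(iy0, iy1 + 1), slice(ix0, ix1 + 1))
            g[v] = float(volumes.green[v][box].mean())
            r[v] = float(volumes.red[v][box].mean())
        green[str(nid)] = g
        red[str(nid)] = r
    if clipped_any:
        logger.warning("one or more ROI boxes were clipped at image borders")
    return RawTraces(
        recording_id=recording_id,
        rate_hz=volumes.volume_rate_hz,
        green=green,
        red=red,
    )


def _block_mean(x: np.ndarray, factor: int) -> np.ndarray:
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def downsample(trace: RawTraces, factor: int = 2) -> RawTraces:
    """Non-overlapping block means; trailing partial block dropped."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"downsampling factor must be an integer >= 1, got {factor}")
    if factor == 1:
        return trace
    return RawTraces(
        recording_id=trace.recording_id,
        rate_hz=trace.rate_hz / factor,
        green={nid: _block_mean(g, factor) for nid, g in trace.green.items()},
        red={nid: _block_mean(r, factor) for nid, r in trace.red.items()},
    )


def savitzky_golay(
    series: np.ndarray, window: int = 13, order: int = 1
) -> np.ndarray:
    """Savitzky-Golay smoothing with reflect padding at the boundaries.

    The order-1 centered case equals a centered moving average on interior
    samples.  Series shorter than the window are rejected rather than
    silently smoothed with a smaller window.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be smaller than window ({window})")
    if series.size < window:
        raise ValueError(
            f"series length {series.size} is shorter than the filter window {window}"
        )
    return savgol_filter(series, window_length=window, polyorder=order, mode="mirror")


def compute_activity_trace(
    raw: RawTraces,
    camera_offset: float = 0.0,
    window: int = 13,
    order: int = 1,
    downsample_factor: int = 2,
) -> ActivityTrace:
    """Smoothed ratiometric activity at the analysis rate.

    ``activity(t) = SG(downsample((G(t) - offset) / (R(t) - offset)))``.
    The ratio is formed at the acquisition rate so a multiplicative factor
    shared by both channels cancels exactly; block-mean downsampling and
    smoothing follow.  The red channel must be strictly positive after
    offset subtraction at every sample.
    """
    if not isinstance(downsample_factor, (int, np.integer)) or downsample_factor < 1:
        raise ValueError(
            f"downsampling factor must be an integer >= 1, got {downsample_factor}"
        )
    activity: dict[str, np.ndarray] = {}
    for nid in sorted(raw.green):
        g = raw.green[nid] - camera_offset
        r = raw.red[nid] - camera_offset
        bad = np.flatnonzero(r <= 0)
        if bad.size:
            t_bad = (bad[0] + 0.5) / raw.rate_hz
            raise ValueError(
                f"non-positive red signal for neuron {nid!r} at t={t_bad:.2f} s "
                "after offset subtraction (tracking or offset failure)"
            )
        ratio = g / r
        if downsample_factor > 1:
            ratio = _block_mean(ratio, downsample_factor)
        activity[nid] = savitzky_golay(ratio, window=window, order=order)
    return ActivityTrace(
        recording_id=raw.recording_id,
        rate_hz=raw.rate_hz / downsample_factor,
        activity=activity,
        provenance={
            "camera_offset": camera_offset,
            "sg_window": window,
            "sg_order": order,
            "downsample_factor": downsample_factor,
            "order_of_operations": "ratio,downsample,smooth",
        },
    )
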