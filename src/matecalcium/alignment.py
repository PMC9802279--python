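"""Event-triggered response analysis.

Aligns activity traces to behavioral motif onsets over a fixed peri-event
window, averages and min-max-normalizes response curves, computes lagged
per-instance cross-correlations against binarized behavior with a one-sample
t-test at the selected lag, and summarizes/compares peak latencies.

Lag sign convention: a positive lag means neural activity follows behavior
(activity at time t is compared with behavior at time t - lag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ethogram import INTERVAL_EVENTS, POINT_EVENTS, Ethogram
from .extraction import ActivityTrace
from .metrics import RankSumResult, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S: tuple[float, float] = (-7.0, 13.0)


@dataclass
class AlignedResponseMatrix:
    """Per-instance event-locked activity windows for one neuron and motif."""

    neuron_id: str
    motif: str
    rate_hz: float
    window_s: tuple[float, float]
    rows: np.ndarray  # (instance, window sample)
    onsets_s: list[float]  # onset time of each included instance
    recording_ids: list[str]
    n_excluded: int = 0

    @property
    def n_instances(self) -> int:
        return self.rows.shape[0]

    @property
    def n_animals(self) -> int:
        return len(set(self.recording_ids))

    def window_times(self) -> np.ndarray:
        lo, hi = self.window_s
        n = self.rows.shape[1]
        return lo + np.arange(n) / self.rate_hz


@dataclass
class ResponseCurve:
    """Dataset-averaged, min-max-normalized response curve."""

    neuron_id: str
    motif: str
    rate_hz: float
    window_s: tuple[float, float]
    curve: np.ndarray
    sd: np.ndarray  # per-sample sd, rescaled by the normalizing affine map
    n_instances: int
    n_animals: int
    constant: bool = False

    def window_times(self) -> np.ndarray:
        lo, hi = self.window_s
        return lo + np.arange(len(self.curve)) / self.rate_hz


@dataclass
class LagCorrelationResult:
    """Lagged correlation between activity windows and binarized behavior."""

    neuron_id: str
    motif: str
    lag_samples: int  # selected lag; positive = activity follows behavior
    lag_s: float
    correlations: np.ndarray  # per instance, at the selected lag
    mean_correlation: float
    t_statistic: float
    p_value: float  # one-sided, H1: mean correlation > 0
    n_instances: int
    n_dropped: int
    mean_correlation_per_lag: dict[int, float] = field(default_factory=dict)
    lag_convention: str = "positive lag = neural activity follows behavior"


@dataclass
class LatencySummary:
    """Per-instance peak times relative to the motif onset."""

    neuron_id: str
    motif: str
    peak_times_s: np.ndarray
    median_s: float
    label: str = ""
    constant_rows: int = 0


def _window_samples(window_s: tuple[float, float], rate_hz: float) -> tuple[int, int]:
    lo = int(round(window_s[0] * rate_hz))
    hi = int(round(window_s[1] * rate_hz))
    return lo, hi


def align_to_events(
    trace: ActivityTrace,
    onsets_s: list[float],
    neuron_id: str,
    motif: str = "",
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
) -> AlignedResponseMatrix:
    """One row per onset whose full peri-event window lies in the recording.

    The onset is snapped to the sample covering it (sample i spans
    ``[i/rate, (i+1)/rate)``), which becomes window time 0.  Instances with
    incomplete windows are excluded and counted.
    """
    x = trace.activity[neuron_id]
    rate = trace.rate_hz
    lo, hi = _window_samples(window_s, rate)
    rows, kept, excluded = [], [], 0
    for onset in onsets_s:
        i0 = int(math.floor(onset * rate + 1e-9))
        if i0 + lo < 0 or i0 + hi > len(x) - 1:
            excluded += 1
            continue
        rows.append(x[i0 + lo : i0 + hi + 1])
        kept.append(float(onset))
    if excluded:
        logger.info(
            "align_to_events: excluded %d of %d instances with incomplete windows",
            excluded,
            len(onsets_s),
        )
    if not rows:
        raise ValueError(
            f"no usable instances for neuron {neuron_id!r} / motif {motif!r} "
            f"({excluded} excluded with incomplete windows)"
        )
    return AlignedResponseMatrix(
        neuron_id=neuron_id,
        motif=motif,
        rate_hz=rate,
        window_s=window_s,
        rows=np.vstack(rows),
        onsets_s=kept,
        recording_ids=[trace.recording_id] * len(kept),
        n_excluded=excluded,
    )


def concatenate_matrices(
    matrices: list[AlignedResponseMatrix],
) -> AlignedResponseMatrix:
    """Pool instances of the same neuron/motif across recordings."""
    first = matrices[0]
    for m in matrices[1:]:
        if (m.neuron_id, m.motif, m.rate_hz, m.window_s) != (
            first.neuron_id,
            first.motif,
            first.rate_hz,
            first.window_s,
        ):
            raise ValueError("matrices are not alignable (mismatched metadata)")
    return AlignedResponseMatrix(
        neuron_id=first.neuron_id,
        motif=first.motif,
        rate_hz=first.rate_hz,
        window_s=first.window_s,
        rows=np.vstack([m.rows for m in matrices]),
        onsets_s=sum((m.onsets_s for m in matrices), []),
        recording_ids=sum((m.recording_ids for m in matrices), []),
        n_excluded=sum(m.n_excluded for m in matrices),
    )


def average_response(
    matrices: list[AlignedResponseMatrix] | AlignedResponseMatrix,
) -> ResponseCurve:
    """Mean over all instances pooled over animals, min-max normalized.

    The per-sample standard deviation is computed before normalization and
    rescaled by the same affine map.  A constant average is returned as an
    all-zero flagged curve with a warning rather than an exception.
    """
    if isinstance(matrices, AlignedResponseMatrix):
        matrices = [matrices]
    pooled = concatenate_matrices(matrices)
    mean = pooled.rows.mean(axis=0)
    sd = pooled.rows.std(axis=0, ddof=0)
    span = mean.max() - mean.min()
    if span == 0:
        logger.warning(
            "average_response: constant average for %s/%s; returning zeros",
            pooled.neuron_id,
            pooled.motif,
        )
        curve = np.zeros_like(mean)
        sd_scaled = np.zeros_like(sd)
        constant = True
    else:
        curve = (mean - mean.min()) / span
        sd_scaled = sd / span
        constant = False
    return ResponseCurve(
        neuron_id=pooled.neuron_id,
        motif=pooled.motif,
        rate_hz=pooled.rate_hz,
        window_s=pooled.window_s,
        curve=curve,
        sd=sd_scaled,
        n_instances=pooled.n_instances,
        n_animals=pooled.n_animals,
        constant=constant,
    )


def binarize_behavior(
    ethograms: dict[str, Ethogram] | Ethogram,
    matrix: AlignedResponseMatrix,
    motif: str,
) -> np.ndarray:
    """Behavior indicator rows on the matrix's window grid.

    Interval motifs are 1 inside the motif's intervals (clipped to the
    window); point motifs are 1 on the sample covering each event time.
    """
    if isinstance(ethograms, Ethogram):
        ethograms = {matrix.recording_ids[i]: ethograms for i in range(matrix.n_instances)}
    rate = matrix.rate_hz
    lo, hi = _window_samples(matrix.window_s, rate)
    n = hi - lo + 1
    out = np.zeros((matrix.n_instances, n))
    for j, (onset, rid) in enumerate(zip(matrix.onsets_s, matrix.recording_ids)):
        e = ethograms[rid]
        i0 = int(math.floor(onset * rate + 1e-9))
        grid = np.arange(i0 + lo, i0 + hi + 1)  # absolute sample indices
        tmid = (grid + 0.5) / rate
        if motif in INTERVAL_EVENTS:
            for on, off in e.intervals_of(motif):
                out[j][(tmid >= on) & (tmid < off)] = 1.0
        elif motif in POINT_EVENTS:
            for t0 in e.points_of(motif):
                k = int(math.floor(t0 * rate + 1e-9)) - (i0 + lo)
                if 0 <= k < n:
                    out[j][k] = 1.0
        else:
            raise ValueError(f"unknown motif {motif!r}")
    return out


def _lagged_correlation(activity: np.ndarray, behavior: np.ndarray, lag: int) -> float:
    """Pearson correlation of activity[t] vs behavior[t - lag], overlap only."""
    if lag > 0:
        a, b = activity[lag:], behavior[:-lag]
    elif lag < 0:
        a, b = activity[:lag], behavior[-lag:]
    else:
        a, b = activity, behavior
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def lag_correlation(
    matrix: AlignedResponseMatrix,
    behavior: dict[str, Ethogram] | Ethogram,
    motif: str | None = None,
    max_lag_samples: int = 5,
) -> LagCorrelationResult:
    """Per-instance lagged Pearson correlations with lag selection and t-test.

    For each lag in ``-max_lag..+max_lag`` the per-instance correlation
    between the activity row and the shifted behavior row is computed
    (overlapping support only); the lag maximizing the absolute mean
    correlation is selected, and a one-sample one-sided t-test (H1: mean
    correlation > 0) is reported at that lag.  Instances whose behavior row
    is constant within the window are dropped and counted.
    """
    motif = motif or matrix.motif
    beh = binarize_behavior(behavior, matrix, motif)
    keep = np.ptp(beh, axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "lag_correlation: dropped %d instances with constant behavior rows",
            n_dropped,
        )
    if not keep.any():
        raise ValueError(
            f"all {matrix.n_instances} instances have constant behavior rows "
            f"for motif {motif!r}"
        )
    act = matrix.rows[keep]
    beh = beh[keep]
    lags = range(-max_lag_samples, max_lag_samples + 1)
    per_lag: dict[int, np.ndarray] = {}
    mean_per_lag: dict[int, float] = {}
    for lag in lags:
        r = np.array(
            [_lagged_correlation(a, b, lag) for a, b in zip(act, beh)]
        )
        per_lag[lag] = r
        mean_per_lag[lag] = float(np.nanmean(r)) if not np.all(np.isnan(r)) else np.nan
    best = max(lags, key=lambda l: abs(mean_per_lag[l]) if not np.isnan(mean_per_lag[l]) else -np.inf)
    r_best = per_lag[best]
    r_best = r_best[~np.isnan(r_best)]
    if r_best.size == 0:
        raise ValueError("no instance yielded a defined correlation")
    if r_best.size > 1 and np.ptp(r_best) > 0:
        t_res = stats.ttest_1samp(r_best, 0.0, alternative="greater")
        t_stat, p = float(t_res.statistic), float(t_res.pvalue)
    else:
        # degenerate: identical correlations; sign decides
        t_stat = math.inf if r_best.mean() > 0 else (-math.inf if r_best.mean() < 0 else 0.0)
        p = 0.0 if r_best.mean() > 0 else 1.0
    return LagCorrelationResult(
        neuron_id=matrix.neuron_id,
        motif=motif,
        lag_samples=int(best),
        lag_s=best / matrix.rate_hz,
        correlations=r_best,
        mean_correlation=float(r_best.mean()),
        t_statistic=t_stat,
        p_value=p,
        n_instances=int(r_best.size),
        n_dropped=n_dropped,
        mean_correlation_per_lag=mean_per_lag,
    )


def peak_latency(
    matrix: AlignedResponseMatrix,
    search_s: tuple[float, float] | None = None,
    label: str = "",
) -> LatencySummary:
    """Per-row time of the maximum sample within the search range.

    Ties resolve to the earliest sample; constant rows peak at the search
    start and are counted in ``constant_rows``.
    """
    if matrix.n_instances < 1:
        raise ValueError("empty aligned matrix")
    times = matrix.window_times()
    if search_s is None:
        search_s = matrix.window_s
    mask = (times >= search_s[0] - 1e-9) & (times <= search_s[1] + 1e-9)
    sub = matrix.rows[:, mask]
    sub_times = times[mask]
    idx = sub.argmax(axis=1)  # argmax takes the earliest maximum
    peaks = sub_times[idx]
    constant = int((np.ptp(sub, axis=1) == 0).sum())
    if constant:
        logger.warning("peak_latency: %d constant rows peak at window start", constant)
    return LatencySummary(
        neuron_id=matrix.neuron_id,
        motif=matrix.motif,
        peak_times_s=peaks,
        median_s=float(np.median(peaks)),
        label=label,
        constant_rows=constant,
    )


def compare_latencies(a: LatencySummary, b: LatencySummary) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum on per-instance peak times."""
    if a.peak_times_s.size == 0 or b.peak_times_s.size == 0:
        raise ValueError("both latency groups must be non-empty")
    return wilcoxon_rank_sum(a.peak_times_s, b.peak_times_s)


def plot_response_curve(curve: ResponseCurve, path: str) -> None:
    """Save the normalized curve with its gray sd band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = curve.window_times()
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.fill_between(
        t, curve.curve - curve.sd, curve.curve + curve.sd, color="0.8", label="sd"
    )
    ax.plot(t, curve.curve, color="k")
    ax.axvline(0.0, color="r", lw=0.8, ls="--")
    ax.set_xlabel("time from onset (s)")
    ax.set_ylabel("normalized activity")
    ax.set_title(
        f"{curve.neuron_id} / {curve.motif} "
        f"(n={curve.n_animals} animals, {curve.n_instances} events)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
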