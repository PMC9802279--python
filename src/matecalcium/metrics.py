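"""Mating-performance measures and cohort comparisons.

Eight per-male performance measures plus a mating success index are computed
from a validated ethogram.  Measures with a zero denominator are reported as
``None`` (undefined), never silently as 0.  Cohorts are compared with a
two-sided Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

from .ethogram import Ethogram, validate_ethogram


@dataclass
class MatingPerformance:
    """Per-male behavioral measures.

    Rates are per minute of the relevant interval duration; ratios are
    dimensionless.  ``None`` marks an undefined (0/0) measure.
    """

    recording_id: str
    turning_success_rate: float | None
    ejaculations_per_ventral_min: float | None
    ejaculations_per_vulva_min: float | None
    spurious_pause_ratio: float | None
    vulva_passes_per_ventral_min: float | None
    mean_vulva_contact_s: float | None
    slide_over_per_ventral_min: float | None
    contact_loss_per_ventral_min: float | None
    mating_success_index: float | None


MEASURES: tuple[str, ...] = tuple(
    f.name for f in fields(MatingPerformance) if f.name != "recording_id"
)


def _per_minute(count: int, duration_s: float) -> float | None:
    if duration_s <= 0:
        return None
    return count / (duration_s / 60.0)


def mating_metrics(e: Ethogram, *, validate: bool = True) -> MatingPerformance:
    """Compute the performance measures for one male.

    Courtship duration runs from the first ventral-contact onset to the
    ejaculation time, or to the recording end if the male never ejaculates.
    """
    if validate:
        report = validate_ethogram(e)
        if not report.ok:
            raise ValueError(
                f"invalid ethogram {e.recording_id}: " + "; ".join(report.violations)
            )

    n_success = e.count("turn_success")
    n_fail = e.count("turn_fail")
    attempts = n_success + n_fail
    turning = n_success / attempts if attempts else None

    ventral_s = e.total_duration_of("ventral_contact")
    vulva_s = e.total_duration_of("vulva_contact")
    pause_s = e.total_duration_of("pause_away_from_vulva")
    n_ej = e.count("ejaculation")

    vulva_lengths = [off - on for on, off in e.intervals_of("vulva_contact")]
    mean_vulva = float(np.mean(vulva_lengths)) if vulva_lengths else None

    ventral_onsets = e.onsets_of("ventral_contact")
    if ventral_onsets:
        ej_times = e.points_of("ejaculation")
        courtship_end = ej_times[0] if ej_times else e.duration_s
        courtship_s = courtship_end - ventral_onsets[0]
    else:
        courtship_s = 0.0

    return MatingPerformance(
        recording_id=e.recording_id,
        turning_success_rate=turning,
        ejaculations_per_ventral_min=_per_minute(n_ej, ventral_s),
        ejaculations_per_vulva_min=_per_minute(n_ej, vulva_s),
        spurious_pause_ratio=(pause_s / vulva_s) if vulva_s > 0 else None,
        vulva_passes_per_ventral_min=_per_minute(e.count("vulva_pass"), ventral_s),
        mean_vulva_contact_s=mean_vulva,
        slide_over_per_ventral_min=_per_minute(e.count("slide_over"), ventral_s),
        contact_loss_per_ventral_min=_per_minute(e.count("loss_of_contact"), ventral_s),
        mating_success_index=_per_minute(n_ej, courtship_s),
    )


def cohort_success_percent(cohort: list[Ethogram]) -> tuple[int, int, int]:
    """(n_success, n_total, floored integer percent) for a cohort.

    A male is successful iff his ethogram contains at least one ejaculation.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n_success = sum(1 for e in cohort if e.count("ejaculation") >= 1)
    n_total = len(cohort)
    return n_success, n_total, math.floor(100 * n_success / n_total)


@dataclass
class RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two samples."""

    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str


def wilcoxon_rank_sum(a, b) -> RankSumResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution for small samples without ties
    (n, m <= 25) and the tie-corrected normal approximation otherwise.
    Degenerate pooled samples (zero rank variance) return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        return RankSumResult(
            statistic=a.size * b.size / 2.0,
            p_value=1.0,
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
            n_a=a.size,
            n_b=b.size,
            method="degenerate",
        )
    if not has_ties and max(a.size, b.size) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=a.size,
        n_b=b.size,
        method=method,
    )


@dataclass
class CohortResult:
    """Between-cohort comparison of one performance measure."""

    measure: str
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    n_undefined_a: int
    n_undefined_b: int
    method: str


def compare_cohorts(
    a: list[MatingPerformance], b: list[MatingPerformance], measure: str
) -> CohortResult:
    """Compare one measure between two cohorts (two-sided rank-sum).

    Undefined per-male values are dropped independently per cohort and the
    exclusion counts reported.
    """
    if measure not in MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; valid measures: " + ", ".join(MEASURES)
        )
    va = [getattr(m, measure) for m in a]
    vb = [getattr(m, measure) for m in b]
    xa = [v for v in va if v is not None]
    xb = [v for v in vb if v is not None]
    if not xa or not xb:
        raise ValueError(
            f"measure {measure!r} undefined for an entire cohort "
            f"(defined: {len(xa)} of {len(va)} vs {len(xb)} of {len(vb)})"
        )
    rs = wilcoxon_rank_sum(xa, xb)
    return CohortResult(
        measure=measure,
        statistic=rs.statistic,
        p_value=rs.p_value,
        median_a=rs.median_a,
        median_b=rs.median_b,
        n_a=rs.n_a,
        n_b=rs.n_b,
        n_undefined_a=len(va) - len(xa),
        n_undefined_b=len(vb) - len(xb),
        method=rs.method,
    )
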