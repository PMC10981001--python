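"""Cohort-level statistics for the two-route uptake tables.

Per-patient derived quantities (peak tumour SUVmax across time points, pooled
parotid SUVmean, tumour-to-organ ratios), intra-patient ssIA/IV fold changes,
and cohort summaries: medians with interquartile ranges under the SPSS
weighted-average ("type 6") quantile convention, means, and paired percentile
bootstrap 95% confidence intervals with patient-level resampling.

Reporting convention: printed statistics are rounded half away from zero to
one decimal (fold changes to integers), matching common clinical-statistics
output.  The EANM-style qualification rule counts patients whose
tumour-to-salivary-gland ratio, rounded to one decimal as tabulated, reaches
the 0.5 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from .cohort_io import ROUTE_IV, ROUTE_SSIA, ROUTES, PatientRecord

__all__ = [
    "weighted_average_quantile",
    "round_half_away",
    "PatientDerived",
    "derive_patient",
    "fold_change",
    "paired_bootstrap_ci",
    "qualification",
    "CohortSummary",
    "summarize",
]


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (SPSS/clinical convention).

    Operates on the shortest decimal representation of ``value`` so that a
    computed 142.75 rounds to 142.8 rather than falling on a binary artefact.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def weighted_average_quantile(values: Sequence[float], p: float) -> float:
    """Weighted-average (SPSS "type 6") quantile estimate.

    The estimate sits at position ``h = (n + 1) * p`` on the sorted sample,
    with linear interpolation between the flanking order statistics and
    clamping to the extremes when ``h`` falls outside ``[1, n]``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise ValueError("cannot take a quantile of an empty list")
    h = (n + 1) * p
    if h <= 1.0:
        return xs[0]
    if h >= n:
        return xs[-1]
    j = int(math.floor(h))
    g = h - j
    return xs[j - 1] + g * (xs[j] - xs[j - 1])


def _median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    return (
        weighted_average_quantile(values, 0.5),
        weighted_average_quantile(values, 0.25),
        weighted_average_quantile(values, 0.75),
    )


@dataclass(frozen=True)
class PatientDerived:
    """Per-patient, per-route summary quantities."""

    patient_id: str
    route: str
    peak_suv_max: float
    pooled_parotid_mean: Optional[float]
    tbr_max: Optional[float]  # None when background unmeasurable at all scans
    tsg_ratio: Optional[float]
    tl_ratio: Optional[float]
    liver_suv_mean: Optional[float]


def derive_patient(record: PatientRecord, route: str) -> PatientDerived:
    """Derive peak SUVmax and tumour-to-organ ratios for one route.

    The per-patient tumour value is the maximum SUVmax over the available
    time points.  The parotid reference is the mean of the per-time-point
    parotid SUVmeans, pooled over every scan where it was read (including
    scans whose tumour value is missing).  TBRmax uses only scans with a
    measurable background and is None when no background was measurable.
    """
    series = record.route(route)
    tumour = [m.suv_max_tumour for m in series.measurements if m.has_tumour_value]
    if not tumour:
        raise ValueError(f"patient {record.patient_id} route {route}: no tumour measurements")
    peak = max(tumour)

    parotids = [m.suv_mean_parotid for m in series.measurements if m.suv_mean_parotid is not None]
    pooled = float(np.mean(parotids)) if parotids else None
    if pooled is not None and pooled == 0:
        raise ValueError(f"patient {record.patient_id} route {route}: zero pooled parotid mean")
    liver = series.suv_mean_liver
    if liver is not None and liver == 0:
        raise ValueError(f"patient {record.patient_id} route {route}: zero liver SUVmean")

    tbrs = [
        m.suv_max_tumour / m.suv_mean_background
        for m in series.measurements
        if m.has_tumour_value
        and isinstance(m.suv_mean_background, float)
        and m.suv_mean_background > 0
    ]
    return PatientDerived(
        patient_id=record.patient_id,
        route=route,
        peak_suv_max=peak,
        pooled_parotid_mean=pooled,
        tbr_max=max(tbrs) if tbrs else None,
        tsg_ratio=peak / pooled if pooled else None,
        tl_ratio=peak / liver if liver else None,
        liver_suv_mean=liver,
    )


def fold_change(record: PatientRecord) -> float:
    """ssIA / IV ratio of the per-patient peak tumour SUVmax."""
    if not record.is_complete:
        raise ValueError(f"patient {record.patient_id}: both routes required for a fold change")
    return (
        derive_patient(record, ROUTE_SSIA).peak_suv_max
        / derive_patient(record, ROUTE_IV).peak_suv_max
    )


def paired_bootstrap_ci(
    x: Sequence[Optional[float]],
    y: Sequence[Optional[float]],
    b: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Mean paired difference ``mean(y - x)`` with a percentile bootstrap CI.

    Pairs are resampled at the subject level with replacement; pairs with a
    missing member are dropped first.  Returns ``(point, lo, hi)``.  The point
    estimate does not depend on the seed; the CI is deterministic given it.
    """
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    pairs = np.array(
        [(a, c) for a, c in zip(x, y) if a is not None and c is not None], dtype=float
    )
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    diffs = pairs[:, 1] - pairs[:, 0]
    point = float(np.mean(diffs))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(int(b), n))
    means = diffs[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo = weighted_average_quantile(means, alpha)
    hi = weighted_average_quantile(means, 1.0 - alpha)
    return point, float(lo), float(hi)


def qualification(cohort: Iterable[PatientRecord], threshold: float = 0.5) -> dict[str, int]:
    """Patients per route whose tabulated (one-decimal) T/SG ratio >= threshold."""
    counts = {r: 0 for r in ROUTES}
    for record in cohort:
        for route in ROUTES:
            if route not in record.series:
                continue
            d = derive_patient(record, route)
            if d.tsg_ratio is None:
                continue
            if round_half_away(d.tsg_ratio, 1) >= threshold:
                counts[route] += 1
    return counts


@dataclass(frozen=True)
class StatSummary:
    median: float
    q1: float
    q3: float
    mean: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must bracket the median")


@dataclass(frozen=True)
class CohortSummary:
    """Everything a pooled two-route uptake table reports."""

    n_patients: int
    per_route: dict[str, dict[str, StatSummary]]
    paired_differences: dict[str, tuple[float, float, float]]
    fold_change_median: float
    fold_change_q1: float
    fold_change_q3: float
    per_timepoint_suvmax: dict[str, dict[int, tuple[float, float, float]]]
    qualification_counts: dict[str, int]
    n_per_route: dict[str, int]


_STATS = ("peak_suv_max", "tsg_ratio", "tl_ratio", "pooled_parotid_mean", "liver_suv_mean", "tbr_max")


def _collect(derived: list[PatientDerived], stat: str) -> list[float]:
    return [getattr(d, stat) for d in derived if getattr(d, stat) is not None]


def summarize(
    cohort: Sequence[PatientRecord],
    bootstrap_b: int = 1000,
    seed: int = 0,
    use_tabulated_ratios: bool = True,
) -> CohortSummary:
    """Cohort summary: medians/IQRs, means, bootstrap CIs, paired differences.

    With ``use_tabulated_ratios`` (default) the tumour-to-organ ratios are
    first rounded to one decimal, as they appear in a per-patient table,
    before pooling — the convention needed to reproduce a published summary
    from its printed per-patient table when the unrounded organ means are
    unavailable.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    derived: dict[str, list[PatientDerived]] = {r: [] for r in ROUTES}
    for record in cohort:
        for route in ROUTES:
            if route in record.series:
                d = derive_patient(record, route)
                if use_tabulated_ratios:
                    series = record.series[route]
                    tsg = series.ref_tsg_ratio
                    if tsg is None and d.tsg_ratio is not None:
                        tsg = round_half_away(d.tsg_ratio)
                    tl = series.ref_tl_ratio
                    if tl is None and d.tl_ratio is not None:
                        tl = round_half_away(d.tl_ratio)
                    d = PatientDerived(
                        patient_id=d.patient_id,
                        route=d.route,
                        peak_suv_max=d.peak_suv_max,
                        pooled_parotid_mean=d.pooled_parotid_mean,
                        tbr_max=d.tbr_max,
                        tsg_ratio=tsg,
                        tl_ratio=tl,
                        liver_suv_mean=d.liver_suv_mean,
                    )
                derived[route].append(d)

    per_route: dict[str, dict[str, StatSummary]] = {}
    for route in ROUTES:
        if not derived[route]:
            continue
        per_route[route] = {}
        for k, stat in enumerate(_STATS):
            vals = _collect(derived[route], stat)
            if not vals:
                continue
            med, q1, q3 = _median_iqr(vals)
            # one bootstrap substream per (route, statistic)
            sub_seed = (seed * 97 + k * 13 + (0 if route == ROUTE_IV else 1)) % (2**31)
            if len(vals) >= 2:
                _, lo, hi = paired_bootstrap_ci([0.0] * len(vals), vals, b=bootstrap_b, seed=sub_seed)
            else:
                lo = hi = vals[0]
            per_route[route][stat] = StatSummary(
                median=med, q1=q1, q3=q3, mean=float(np.mean(vals)), ci_lo=lo, ci_hi=hi
            )

    # paired route differences on patients with both routes
    paired: dict[str, tuple[float, float, float]] = {}
    complete = [r for r in cohort if r.is_complete]
    if len(complete) >= 2:
        by_route = {
            route: {d.patient_id: d for d in derived[route]} for route in ROUTES
        }
        for k, stat in enumerate(_STATS):
            xs, ys = [], []
            for r in complete:
                div = by_route[ROUTE_IV].get(r.patient_id)
                dia = by_route[ROUTE_SSIA].get(r.patient_id)
                xs.append(None if div is None else getattr(div, stat))
                ys.append(None if dia is None else getattr(dia, stat))
            if sum(1 for a, c in zip(xs, ys) if a is not None and c is not None) >= 2:
                paired[stat] = paired_bootstrap_ci(
                    xs, ys, b=bootstrap_b, seed=(seed * 193 + k * 29) % (2**31)
                )

    folds = [fold_change(r) for r in complete] or [1.0]
    fmed, fq1, fq3 = _median_iqr(folds)

    per_tp: dict[str, dict[int, tuple[float, float, float]]] = {}
    for route in ROUTES:
        per_tp[route] = {}
        for scan in (1, 2, 3):
            vals = [
                m.suv_max_tumour
                for r in cohort
                if route in r.series
                for m in r.series[route].measurements
                if m.scan_index == scan and m.has_tumour_value
            ]
            if vals:
                per_tp[route][scan] = _median_iqr(vals)

    return CohortSummary(
        n_patients=len(cohort),
        per_route=per_route,
        paired_differences=paired,
        fold_change_median=fmed,
        fold_change_q1=fq1,
        fold_change_q3=fq3,
        per_timepoint_suvmax=per_tp,
        qualification_counts=qualification(cohort),
        n_per_route={r: len(derived[r]) for r in ROUTES},
    )
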