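"""Orchestration: one-call reproduction of the reference cohort statistics
and a composable multi-stage pipeline (summarise → fit → dose) over any
cohort CSV.

``reproduce_reference`` recomputes every headline statistic of the packaged
two-route clinical cohort from its per-patient table and flags each against
the published reference value; the comparison is exact after the same
one-decimal reporting rounding the source tables use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .cohort_io import ROUTE_IV, ROUTE_SSIA, PatientRecord, read_cohort, table3_fixture
from .cohort_stats import CohortSummary, fold_change, round_half_away, summarize
from .dosimetry import dose_per_cycle, load_nuclides
from .tac_kinetics import build_tac, fit_tac

__all__ = ["REFERENCE_VALUES", "reproduce_reference", "RunConfig", "run_pipeline", "render_summary"]

log = logging.getLogger("ssia_dosekit.pipeline")

#: published reference statistics for the packaged cohort (one-decimal scale)
REFERENCE_VALUES = {
    "median_ssia_peak_suvmax": 142.8,
    "iqr_lo_ssia_peak_suvmax": 102.8,
    "iqr_hi_ssia_peak_suvmax": 245.9,
    "mean_ssia_peak_suvmax": 168.8,
    "mean_iv_peak_suvmax": 10.5,
    "median_fold_change": 15.0,
    "median_tsg_ssia": 8.4,
    "median_tsg_iv": 0.5,
    "median_tl_ssia": 26.5,
    "mean_parotid_suvmean_ssia": 20.7,
    "qualification_ssia": 10.0,
    "qualification_iv": 6.0,
    "patient2_fold_change": 26.0,
    "mean_diff_peak_suvmax": 158.3,
}


def compute_reference_statistics(
    cohort: Optional[list[PatientRecord]] = None,
    bootstrap_b: int = 1000,
    seed: int = 42,
) -> tuple[dict[str, float], CohortSummary]:
    """The headline cohort statistics, rounded as reported."""
    cohort = cohort if cohort is not None else table3_fixture()
    s = summarize(cohort, bootstrap_b=bootstrap_b, seed=seed)
    ia = s.per_route[ROUTE_SSIA]
    iv = s.per_route[ROUTE_IV]
    patient2 = next(r for r in cohort if r.patient_id == "2")
    values = {
        "median_ssia_peak_suvmax": round_half_away(ia["peak_suv_max"].median),
        "iqr_lo_ssia_peak_suvmax": round_half_away(ia["peak_suv_max"].q1),
        "iqr_hi_ssia_peak_suvmax": round_half_away(ia["peak_suv_max"].q3),
        "mean_ssia_peak_suvmax": round_half_away(ia["peak_suv_max"].mean),
        "mean_iv_peak_suvmax": round_half_away(iv["peak_suv_max"].mean),
        "median_fold_change": round_half_away(s.fold_change_median, 0),
        "median_tsg_ssia": round_half_away(ia["tsg_ratio"].median),
        "median_tsg_iv": round_half_away(iv["tsg_ratio"].median),
        "median_tl_ssia": round_half_away(ia["tl_ratio"].median),
        "mean_parotid_suvmean_ssia": round_half_away(ia["pooled_parotid_mean"].mean),
        "qualification_ssia": float(s.qualification_counts[ROUTE_SSIA]),
        "qualification_iv": float(s.qualification_counts[ROUTE_IV]),
        "patient2_fold_change": round_half_away(fold_change(patient2), 0),
        "mean_diff_peak_suvmax": round_half_away(s.paired_differences["peak_suv_max"][0]),
    }
    return values, s


def reproduce_reference(bootstrap_b: int = 1000, seed: int = 42) -> dict:
    """Recompute the reference cohort statistics and flag each pass/fail."""
    values, summary = compute_reference_statistics(bootstrap_b=bootstrap_b, seed=seed)
    targets = {
        name: {
            "value": values[name],
            "expected": REFERENCE_VALUES[name],
            "pass": values[name] == REFERENCE_VALUES[name],
        }
        for name in REFERENCE_VALUES
    }
    report = {
        "targets": targets,
        "all_pass": all(t["pass"] for t in targets.values()),
        "n_patients": summary.n_patients,
        "bootstrap_b": bootstrap_b,
        "seed": seed,
    }
    log.info("reference reproduction: %d/%d targets pass",
             sum(t["pass"] for t in targets.values()), len(targets))
    return report


def render_summary(s: CohortSummary) -> str:
    """Human-readable text table mirroring a pooled two-route uptake table."""
    rows = [
        ("peak SUVmax", "peak_suv_max"),
        ("TBRmax", "tbr_max"),
        ("SUVmean liver", "liver_suv_mean"),
        ("T/L ratio", "tl_ratio"),
        ("SUVmean parotid", "pooled_parotid_mean"),
        ("T/SG ratio", "tsg_ratio"),
    ]
    def f1(v: float) -> str:
        return f"{round_half_away(v):.1f}"

    out = [f"Cohort summary (n={s.n_patients}); median (IQR) per route"]
    header = f"{'statistic':<18}{'IV':>24}{'ssIA':>24}{'mean diff (95% CI)':>28}"
    out.append(header)
    out.append("-" * len(header))
    for label, stat in rows:
        cells = []
        for route in (ROUTE_IV, ROUTE_SSIA):
            st = s.per_route.get(route, {}).get(stat)
            cells.append(
                "-" if st is None
                else f"{f1(st.median)} ({f1(st.q1)}-{f1(st.q3)})"
            )
        diff = s.paired_differences.get(stat)
        cells.append("-" if diff is None else f"{f1(diff[0])} ({f1(diff[1])} to {f1(diff[2])})")
        out.append(f"{label:<18}{cells[0]:>24}{cells[1]:>24}{cells[2]:>28}")
    out.append(
        f"fold change (ssIA/IV): median {s.fold_change_median:.0f} "
        f"(IQR {s.fold_change_q1:.0f}-{s.fold_change_q3:.0f})"
    )
    q = s.qualification_counts
    out.append(
        f"T/SG >= 0.5 qualification: ssIA {q[ROUTE_SSIA]}/{s.n_per_route[ROUTE_SSIA]}, "
        f"IV {q[ROUTE_IV]}/{s.n_per_route[ROUTE_IV]}"
    )
    return "\n".join(out)


@dataclass
class RunConfig:
    """Configuration for a multi-stage pipeline run."""

    cohort_path: Path
    out_dir: Path
    bootstrap_b: int = 1000
    seed: int = 42
    nuclide_table: Optional[Path] = None
    nuclides: tuple[str, ...] = ("lu177", "ac225")
    model_activity_mbq: dict = field(
        default_factory=lambda: {"lu177": 7400.0, "ac225": 8.0}
    )
    stages: tuple[str, ...] = ("summarize", "fit", "dose")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the configured stages, writing one JSON artifact per stage."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.cohort_path)
    artifacts: dict[str, Path] = {}

    if "summarize" in config.stages:
        _, s = compute_reference_statistics(cohort, config.bootstrap_b, config.seed)
        path = config.out_dir / "summary.json"
        path.write_text(_summary_json(s))
        artifacts["summarize"] = path
        log.info("stage summarize -> %s", path)

    fits: dict[tuple[str, str], dict] = {}
    if "fit" in config.stages or "dose" in config.stages:
        for record in cohort:
            for route, series in record.series.items():
                if record.body_weight_kg is None or record.uptake_volume_ml is None:
                    continue
                activity = series.injected_activity_mbq or 100.0
                tac = build_tac(series, record.body_weight_kg, record.uptake_volume_ml, activity)
                if len(tac.times_h) < 2:
                    continue
                fit = fit_tac(tac.times_h, tac.activity_mbq)
                fits[(record.patient_id, route)] = json.loads(fit.to_json())
    if "fit" in config.stages:
        path = config.out_dir / "fits.json"
        path.write_text(json.dumps({f"{p}/{r}": f for (p, r), f in sorted(fits.items())}, indent=2))
        artifacts["fit"] = path
        log.info("stage fit -> %s", path)

    if "dose" in config.stages:
        table = load_nuclides(config.nuclide_table)
        doses = {}
        for record in cohort:
            if record.body_weight_kg is None or record.tumour_ce_volume_ml is None:
                continue
            for route in record.series:
                for name in config.nuclides:
                    if name not in table:
                        raise KeyError(
                            f"unknown nuclide {name!r}; available: {sorted(table)}"
                        )
                    est = dose_per_cycle(
                        record, route, table[name], config.model_activity_mbq[name]
                    )
                    doses[f"{record.patient_id}/{route}/{name}"] = {
                        "dose_gy": est.dose_gy,
                        "rbe_weighted_dose_gy": est.rbe_weighted_dose_gy,
                        "a_tilde_mbq_h": est.a_tilde_mbq_h,
                        "tia_model": est.tia_model,
                        "teq_h": est.teq_h,
                    }
        path = config.out_dir / "doses.json"
        path.write_text(json.dumps(doses, indent=2, sort_keys=True))
        artifacts["dose"] = path
        log.info("stage dose -> %s", path)
    return artifacts


def _summary_json(s: CohortSummary) -> str:
    def stat(st):
        return {
            "median": st.median, "q1": st.q1, "q3": st.q3, "mean": st.mean,
            "ci95": [st.ci_lo, st.ci_hi],
        }

    return json.dumps(
        {
            "n_patients": s.n_patients,
            "per_route": {
                route: {k: stat(v) for k, v in stats.items()}
                for route, stats in s.per_route.items()
            },
            "paired_differences": {
                k: {"mean_diff": v[0], "ci95": [v[1], v[2]]}
                for k, v in s.paired_differences.items()
            },
            "fold_change": {
                "median": s.fold_change_median,
                "q1": s.fold_change_q1,
                "q3": s.fold_change_q3,
            },
            "qualification_counts": s.qualification_counts,
        },
        indent=2,
        sort_keys=True,
    )
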