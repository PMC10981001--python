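"""Cohort data model and CSV I/O for per-patient PET uptake tables.

The central objects mirror a two-route brain-tumour PET study: each patient is
scanned at up to three time points after intravenous (IV) and after
super-selective intra-arterial (ssIA) administration of a ⁶⁸Ga-labelled PSMA
ligand, and each scan yields tumour SUVmax, contralateral healthy-brain
(background) SUVmean and pooled parotid-gland SUVmean.  Liver SUVmean is
measured once per route on the whole-body scan that follows the first brain
scan.

The on-disk format is a long CSV (one row per patient x route x scan) so a
cohort is trivially diffable; route-level values (liver, injected activity)
and patient-level metadata (weight, volumes) ride on the scan-1 row.  A
background SUVmean below the scanner's measurable floor is encoded with the
explicit sentinel token ``<0.01`` rather than zero, because a zero background
would silently make tumour-to-background ratios infinite.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "UNMEASURABLE",
    "Unmeasurable",
    "ROUTE_IV",
    "ROUTE_SSIA",
    "ROUTES",
    "UptakeMeasurement",
    "RouteSeries",
    "PatientRecord",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "table3_fixture",
]

log = logging.getLogger("ssia_dosekit.cohort_io")

ROUTE_IV = "IV"
ROUTE_SSIA = "ssIA"
ROUTES = (ROUTE_IV, ROUTE_SSIA)

#: sentinel token used on disk for backgrounds below the measurable floor
UNMEASURABLE_TOKEN = "<0.01"


class Unmeasurable:
    """Marker for a background SUVmean below the measurable floor (< 0.01)."""

    _instance: Optional["Unmeasurable"] = None

    def __new__(cls) -> "Unmeasurable":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNMEASURABLE"


UNMEASURABLE = Unmeasurable()

BackgroundValue = Union[float, Unmeasurable, None]


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV does not match the expected schema."""


CSV_COLUMNS = [
    "patient_id",
    "route",
    "scan_index",
    "time_min",
    "suv_max_tumour",
    "suv_mean_background",
    "suv_mean_parotid",
    "suv_mean_liver",
    "body_weight_kg",
    "injected_activity_mbq",
    "tumour_ce_volume_ml",
    "uptake_volume_ml",
    "ref_tbr_max",
    "ref_tsg_ratio",
    "ref_tl_ratio",
]


@dataclass(frozen=True)
class UptakeMeasurement:
    """One (route, time point) row of SUV statistics.

    ``suv_max_tumour`` may be None for a partial measurement: a scan where the
    tumour value is unavailable but organ values (parotid) were still read.
    ``suv_mean_background`` is a float, None (not recorded) or UNMEASURABLE.
    ``ref_tbr_max`` carries a tabulated tumour-to-background ratio from a
    source table, retained as a reference field; it is never recomputed here.
    """

    patient_id: str
    route: str
    scan_index: int
    time_min: float
    suv_max_tumour: Optional[float] = None
    suv_mean_background: BackgroundValue = None
    suv_mean_parotid: Optional[float] = None
    ref_tbr_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        if not 1 <= self.scan_index:
            raise ValueError("scan_index must be >= 1")
        for name in ("suv_max_tumour", "suv_mean_parotid"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        bg = self.suv_mean_background
        if isinstance(bg, float) and bg < 0:
            raise ValueError(f"suv_mean_background must be >= 0, got {bg}")

    @property
    def time_h(self) -> float:
        return self.time_min / 60.0

    @property
    def has_tumour_value(self) -> bool:
        return self.suv_max_tumour is not None


@dataclass(frozen=True)
class RouteSeries:
    """All measurements of one administration route for one patient."""

    route: str
    measurements: tuple[UptakeMeasurement, ...]
    suv_mean_liver: Optional[float] = None
    injected_activity_mbq: Optional[float] = None
    ref_tsg_ratio: Optional[float] = None
    ref_tl_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("a RouteSeries needs at least one measurement")
        if self.suv_mean_liver is not None and self.suv_mean_liver < 0:
            raise ValueError("liver SUVmean must be >= 0")
        idx = [m.scan_index for m in self.measurements]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate scan_index in route {self.route}: {idx}")
        times = [m.time_min for m in sorted(self.measurements, key=lambda m: m.scan_index)]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"scan times must strictly increase with scan_index: {times}")

    @property
    def tumour_measurements(self) -> tuple[UptakeMeasurement, ...]:
        return tuple(m for m in self.measurements if m.has_tumour_value)

    @property
    def n_tumour_measurements(self) -> int:
        return len(self.tumour_measurements)


@dataclass(frozen=True)
class PatientRecord:
    """One study subject: metadata plus per-route measurement series."""

    patient_id: str
    series: Mapping[str, RouteSeries] = field(default_factory=dict)
    body_weight_kg: Optional[float] = None
    tumour_ce_volume_ml: Optional[float] = None
    uptake_volume_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.body_weight_kg is not None and self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        for name in ("tumour_ce_volume_ml", "uptake_volume_ml"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when present")
        object.__setattr__(self, "series", dict(self.series))

    @property
    def is_complete(self) -> bool:
        """Both administration routes present."""
        return all(r in self.series for r in ROUTES)

    def route(self, route: str) -> RouteSeries:
        try:
            return self.series[route]
        except KeyError:
            raise KeyError(f"patient {self.patient_id} has no {route} series") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.body_weight_kg == other.body_weight_kg
            and self.tumour_ce_volume_ml == other.tumour_ce_volume_ml
            and self.uptake_volume_ml == other.uptake_volume_ml
            and dict(self.series) == dict(other.series)
        )


# ---------------------------------------------------------------------------
# CSV serialisation


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    if isinstance(value, Unmeasurable):
        return UNMEASURABLE_TOKEN
    f = float(value)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def _parse_float(cell: str, column: str, line: int) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        raise CohortSchemaError(
            f"line {line}: column {column!r} has non-numeric value {cell!r}"
        ) from None


def _parse_background(cell: str, line: int) -> BackgroundValue:
    cell = cell.strip()
    if cell == UNMEASURABLE_TOKEN:
        return UNMEASURABLE
    value = _parse_float(cell, "suv_mean_background", line)
    if value is not None and value < 0.01 and value != 0.0:
        # a recorded value below the floor is still treated as unmeasurable
        return UNMEASURABLE
    return value


def read_cohort(path: Union[str, Path]) -> list[PatientRecord]:
    """Read a long-format cohort CSV into a list of :class:`PatientRecord`.

    Rows with a blank tumour SUV but at least one other SUV value become
    partial measurements; rows with every SUV cell blank are kept only for
    the route/patient metadata they carry.  Duplicate (patient, route,
    scan_index) triples and schema mismatches raise :class:`CohortSchemaError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortSchemaError(f"{path}: empty file, expected header") from None
        if header != CSV_COLUMNS:
            missing = [c for c in CSV_COLUMNS if c not in header]
            extra = [c for c in header if c not in CSV_COLUMNS]
            raise CohortSchemaError(
                f"{path}: header mismatch (missing columns {missing}, unexpected {extra})"
            )
        rows = [(i + 2, row) for i, row in enumerate(reader) if any(cell.strip() for cell in row)]

    seen: set[tuple[str, str, int]] = set()
    patients: dict[str, dict] = {}
    for line, row in rows:
        if len(row) != len(CSV_COLUMNS):
            raise CohortSchemaError(f"{path} line {line}: expected {len(CSV_COLUMNS)} cells")
        cells = dict(zip(CSV_COLUMNS, row))
        pid = cells["patient_id"].strip()
        route = cells["route"].strip()
        if route not in ROUTES:
            raise CohortSchemaError(f"{path} line {line}: unknown route {route!r}")
        scan_raw = _parse_float(cells["scan_index"], "scan_index", line)
        if scan_raw is None:
            raise CohortSchemaError(f"{path} line {line}: scan_index is required")
        scan = int(scan_raw)
        key = (pid, route, scan)
        if key in seen:
            raise CohortSchemaError(
                f"{path} line {line}: duplicate (patient, route, scan_index) {key}"
            )
        seen.add(key)

        time_min = _parse_float(cells["time_min"], "time_min", line)
        suv_max = _parse_float(cells["suv_max_tumour"], "suv_max_tumour", line)
        background = _parse_background(cells["suv_mean_background"], line)
        parotid = _parse_float(cells["suv_mean_parotid"], "suv_mean_parotid", line)

        entry = patients.setdefault(
            pid, {"meta": {}, "routes": {r: {"meta": {}, "measurements": []} for r in ROUTES}}
        )
        rentry = entry["routes"][route]

        for col, target in (
            ("body_weight_kg", entry["meta"]),
            ("tumour_ce_volume_ml", entry["meta"]),
            ("uptake_volume_ml", entry["meta"]),
            ("suv_mean_liver", rentry["meta"]),
            ("injected_activity_mbq", rentry["meta"]),
            ("ref_tsg_ratio", rentry["meta"]),
            ("ref_tl_ratio", rentry["meta"]),
        ):
            v = _parse_float(cells[col], col, line)
            if v is not None:
                target[col] = v

        has_suv = suv_max is not None or parotid is not None or isinstance(
            background, (float, Unmeasurable)
        )
        if not has_suv:
            log.debug("dropping empty measurement row: %s", key)
            continue
        if time_min is None:
            raise CohortSchemaError(f"{path} line {line}: time_min required for a measurement row")
        rentry["measurements"].append(
            UptakeMeasurement(
                patient_id=pid,
                route=route,
                scan_index=scan,
                time_min=time_min,
                suv_max_tumour=suv_max,
                suv_mean_background=background,
                suv_mean_parotid=parotid,
                ref_tbr_max=_parse_float(cells["ref_tbr_max"], "ref_tbr_max", line),
            )
        )

    cohort: list[PatientRecord] = []
    for pid, entry in patients.items():
        series = {}
        for route, rentry in entry["routes"].items():
            if not rentry["measurements"]:
                continue
            series[route] = RouteSeries(
                route=route,
                measurements=tuple(sorted(rentry["measurements"], key=lambda m: m.scan_index)),
                suv_mean_liver=rentry["meta"].get("suv_mean_liver"),
                injected_activity_mbq=rentry["meta"].get("injected_activity_mbq"),
                ref_tsg_ratio=rentry["meta"].get("ref_tsg_ratio"),
                ref_tl_ratio=rentry["meta"].get("ref_tl_ratio"),
            )
        cohort.append(
            PatientRecord(
                patient_id=pid,
                series=series,
                body_weight_kg=entry["meta"].get("body_weight_kg"),
                tumour_ce_volume_ml=entry["meta"].get("tumour_ce_volume_ml"),
                uptake_volume_ml=entry["meta"].get("uptake_volume_ml"),
            )
        )
    log.info("read %d patients from %s", len(cohort), path)
    return cohort


def write_cohort(cohort: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    """Write a cohort to long-format CSV; inverse of :func:`read_cohort`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for record in cohort:
            for route in ROUTES:
                series = record.series.get(route)
                if series is None:
                    continue
                for i, m in enumerate(sorted(series.measurements, key=lambda m: m.scan_index)):
                    first = i == 0
                    writer.writerow(
                        [
                            record.patient_id,
                            route,
                            str(m.scan_index),
                            _fmt(m.time_min),
                            _fmt(m.suv_max_tumour),
                            _fmt(m.suv_mean_background),
                            _fmt(m.suv_mean_parotid),
                            _fmt(series.suv_mean_liver) if first else "",
                            _fmt(record.body_weight_kg) if first else "",
                            _fmt(series.injected_activity_mbq) if first else "",
                            _fmt(record.tumour_ce_volume_ml) if first else "",
                            _fmt(record.uptake_volume_ml) if first else "",
                            _fmt(m.ref_tbr_max),
                            _fmt(series.ref_tsg_ratio) if first else "",
                            _fmt(series.ref_tl_ratio) if first else "",
                        ]
                    )
    log.info("wrote cohort to %s", path)


def table3_fixture() -> list[PatientRecord]:
    """The packaged reference cohort: 10 patients, IV and ssIA series.

    These are the published per-patient uptake values of the two-route
    clinical study the package models (tumour SUVmax at three time points,
    parotid and liver SUVmeans, and the tabulated tumour-to-organ ratios as
    reference fields).  Body weights, injected activities and tumour volumes
    were not published per patient and are therefore blank; downstream
    dosimetry requires them from configuration or synthetic data.
    """
    with resources.as_file(
        resources.files("ssia_dosekit").joinpath("data/table3.csv")
    ) as p:
        return read_cohort(p)


def with_metadata(
    record: PatientRecord,
    *,
    body_weight_kg: Optional[float] = None,
    tumour_ce_volume_ml: Optional[float] = None,
    uptake_volume_ml: Optional[float] = None,
) -> PatientRecord:
    """Return a copy of ``record`` with metadata fields filled in."""
    return replace(
        record,
        body_weight_kg=body_weight_kg or record.body_weight_kg,
        tumour_ce_volume_ml=tumour_ce_volume_ml or record.tumour_ce_volume_ml,
        uptake_volume_ml=uptake_volume_ml or record.uptake_volume_ml,
    )
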