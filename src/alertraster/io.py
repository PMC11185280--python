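"""CSV reading/writing for the three event logs and the result tables.

Input schemas (all timestamps ISO 8601 minute precision, local wall-clock):

- cases.csv: ``case_id,admission_ts,discharge_ts``
- prescriptions.csv: ``rx_id,case_id,drug_code,route,schedule_kind,start_ts,end_ts``
- alerts.csv: ``alert_id,case_id,alert_type,severity,interactive,trigger_rx_ids,
  display_start_ts,display_end_ts`` — one row per display segment;
  ``trigger_rx_ids`` is semicolon-separated. Rows sharing an alert_id are
  merged into one alert carrying all segments.

These schemas are a canonicalization of a CPOE export, not a vendor format.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import pandas as pd

from .classify import AlertOutcome, ExclusionReason, Status
from .model import (
    AlertRecord,
    AlertType,
    Dataset,
    PatientCase,
    PrescriptionRecord,
    ScheduleKind,
    SchemaError,
    Severity,
)

TS_FORMAT = "%Y-%m-%dT%H:%M"

CASE_COLUMNS = ["case_id", "admission_ts", "discharge_ts"]
RX_COLUMNS = ["rx_id", "case_id", "drug_code", "route", "schedule_kind", "start_ts", "end_ts"]
ALERT_COLUMNS = [
    "alert_id", "case_id", "alert_type", "severity", "interactive",
    "trigger_rx_ids", "display_start_ts", "display_end_ts",
]
OUTCOME_COLUMNS = [
    "alert_id", "case_id", "alert_type", "status", "exclusion_reason",
    "first_index", "last_index", "ddoa_days", "absence_index",
]

RESULT_FILES = ["outcomes.csv", "summary.csv", "pairwise_tests.csv", "curves.csv", "run_report.json"]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _parse_ts(value: str, path: str | Path, row: int, column: str) -> datetime:
    try:
        return datetime.strptime(value, TS_FORMAT)
    except ValueError:
        # allow second precision as a convenience
        try:
            return datetime.fromisoformat(value)
        except ValueError:
            raise SchemaError(
                f"{path} row {row}: unparseable timestamp {value!r} in column {column}"
            ) from None


def fmt_ts(ts: datetime) -> str:
    return ts.strftime(TS_FORMAT)


def load_dataset(
    case_path: str | Path, rx_path: str | Path, alert_path: str | Path
) -> Dataset:
    """Read and validate the three event logs into a Dataset.

    Multiple display-segment rows with the same alert_id are merged into one
    AlertRecord with sorted, normalized segments.
    """
    cases_df = _read_table(case_path, CASE_COLUMNS)
    cases = [
        PatientCase(
            case_id=row.case_id,
            admission_ts=_parse_ts(row.admission_ts, case_path, i + 2, "admission_ts"),
            discharge_ts=_parse_ts(row.discharge_ts, case_path, i + 2, "discharge_ts"),
        )
        for i, row in enumerate(cases_df.itertuples(index=False))
    ]

    rx_df = _read_table(rx_path, RX_COLUMNS)
    prescriptions = []
    for i, row in enumerate(rx_df.itertuples(index=False)):
        try:
            kind = ScheduleKind(row.schedule_kind)
        except ValueError:
            raise SchemaError(
                f"{rx_path} row {i + 2}: unknown schedule_kind {row.schedule_kind!r}"
            ) from None
        prescriptions.append(
            PrescriptionRecord(
                rx_id=row.rx_id,
                case_id=row.case_id,
                drug_code=row.drug_code,
                route=row.route,
                schedule_kind=kind,
                start_ts=_parse_ts(row.start_ts, rx_path, i + 2, "start_ts"),
                end_ts=_parse_ts(row.end_ts, rx_path, i + 2, "end_ts"),
            )
        )

    alert_df = _read_table(alert_path, ALERT_COLUMNS)
    grouped: dict[str, dict] = {}
    for i, row in enumerate(alert_df.itertuples(index=False)):
        seg = (
            _parse_ts(row.display_start_ts, alert_path, i + 2, "display_start_ts"),
            _parse_ts(row.display_end_ts, alert_path, i + 2, "display_end_ts"),
        )
        try:
            atype = AlertType(row.alert_type)
            severity = Severity(row.severity)
        except ValueError as exc:
            raise SchemaError(f"{alert_path} row {i + 2}: {exc}") from None
        if row.interactive not in ("true", "false"):
            raise SchemaError(
                f"{alert_path} row {i + 2}: interactive must be 'true' or 'false'"
            )
        triggers = frozenset(t for t in row.trigger_rx_ids.split(";") if t)
        entry = grouped.setdefault(
            row.alert_id,
            dict(case_id=row.case_id, alert_type=atype, severity=severity,
                 interactive=row.interactive == "true", trigger_rx_ids=triggers,
                 segments=[]),
        )
        entry["segments"].append(seg)
    alerts = [
        AlertRecord(
            alert_id=alert_id,
            case_id=e["case_id"],
            alert_type=e["alert_type"],
            severity=e["severity"],
            interactive=e["interactive"],
            trigger_rx_ids=e["trigger_rx_ids"],
            display_segments=e["segments"],
        )
        for alert_id, e in grouped.items()
    ]

    ds = Dataset(cases=cases, prescriptions=prescriptions, alerts=alerts)
    ds.validate()
    return ds


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a Dataset back to the three input CSVs (round-trip inverse of
    load_dataset)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"case_id": c.case_id, "admission_ts": fmt_ts(c.admission_ts),
             "discharge_ts": fmt_ts(c.discharge_ts)}
            for c in dataset.cases
        ],
        columns=CASE_COLUMNS,
    ).to_csv(out / "cases.csv", index=False)
    pd.DataFrame(
        [
            {"rx_id": p.rx_id, "case_id": p.case_id, "drug_code": p.drug_code,
             "route": p.route, "schedule_kind": p.schedule_kind.value,
             "start_ts": fmt_ts(p.start_ts), "end_ts": fmt_ts(p.end_ts)}
            for p in dataset.prescriptions
        ],
        columns=RX_COLUMNS,
    ).to_csv(out / "prescriptions.csv", index=False)
    alert_rows = []
    for a in dataset.alerts:
        for s, e in a.display_segments:
            alert_rows.append({
                "alert_id": a.alert_id, "case_id": a.case_id,
                "alert_type": a.alert_type.value, "severity": a.severity.value,
                "interactive": "true" if a.interactive else "false",
                "trigger_rx_ids": ";".join(sorted(a.trigger_rx_ids)),
                "display_start_ts": fmt_ts(s), "display_end_ts": fmt_ts(e),
            })
    pd.DataFrame(alert_rows, columns=ALERT_COLUMNS).to_csv(out / "alerts.csv", index=False)
    return {name: out / f"{name}.csv" for name in ("cases", "prescriptions", "alerts")}


def outcomes_to_frame(outcomes: list[AlertOutcome]) -> pd.DataFrame:
    rows = [
        {
            "alert_id": o.alert_id, "case_id": o.case_id,
            "alert_type": o.alert_type.value, "status": o.status.value,
            "exclusion_reason": o.exclusion_reason.value,
            "first_index": o.first_index, "last_index": o.last_index,
            "ddoa_days": o.ddoa_days,
            "absence_index": "" if o.absence_index is None else o.absence_index,
        }
        for o in outcomes
    ]
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def read_outcomes(path: str | Path) -> list[AlertOutcome]:
    df = _read_table(path, OUTCOME_COLUMNS)
    return [
        AlertOutcome(
            alert_id=row.alert_id,
            case_id=row.case_id,
            alert_type=AlertType(row.alert_type),
            status=Status(row.status),
            exclusion_reason=ExclusionReason(row.exclusion_reason),
            first_index=int(row.first_index),
            last_index=int(row.last_index),
            ddoa_days=int(row.ddoa_days),
            absence_index=int(row.absence_index) if row.absence_index else None,
        )
        for row in df.itertuples(index=False)
    ]


def write_results(
    outcomes: list[AlertOutcome],
    summary: pd.DataFrame,
    tests: pd.DataFrame,
    curves: pd.DataFrame,
    out_dir: str | Path,
    report_extra: dict | None = None,
) -> dict[str, Path]:
    """Write outcomes/summary/pairwise-test/curve tables plus a JSON run
    report; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outcomes_to_frame(outcomes).to_csv(out / "outcomes.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    tests.to_csv(out / "pairwise_tests.csv", index=False)
    curves.to_csv(out / "curves.csv", index=False)
    report = {
        "n_outcomes": len(outcomes),
        "counts": {
            status.value: sum(o.status is status for o in outcomes) for status in Status
        },
        "files": RESULT_FILES,
    }
    if report_extra:
        report.update(report_extra)
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return {name: out / name for name in RESULT_FILES}
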