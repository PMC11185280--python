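"""Domain types for CPOE/CDSS event logs.

The analysis consumes three event streams exported from a computerized
physician order entry (CPOE) system with an integrated clinical decision
support system (CDSS): patient cases (inpatient stays), prescriptions, and
medication-alert display records. All timestamps are naive local wall-clock
times at minute precision; daylight-saving transitions are out of scope
because the downstream 24-hour bucketing keys on the calendar date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum


class ScheduleKind(str, Enum):
    """How a prescription is scheduled."""

    REGULAR = "regular"
    AS_NEEDED = "as_needed"
    ONE_TIME = "one_time"


class AlertType(str, Enum):
    """Alert categories issued by the CDSS.

    DDI: drug-drug interaction; DAI: drug-allergy interaction;
    DP: duplicate prescription; PIM: potentially inappropriate medication
    for the elderly; PE_MDD: prescription exceeding the maximum
    recommended daily dose.
    """

    DDI = "DDI"
    DAI = "DAI"
    DP = "DP"
    PIM = "PIM"
    PE_MDD = "PE_MDD"


class Severity(str, Enum):
    """Ordinal alert severity (carried through; not used by classification)."""

    CONTRAINDICATED = "contraindicated"
    SEVERE = "severe"
    MODERATE = "moderate"


class ValidationError(ValueError):
    """A record violates a type invariant."""


class IntegrityError(ValueError):
    """A cross-record reference does not resolve."""


class SchemaError(ValueError):
    """An input file does not conform to the expected CSV schema."""


#: Tolerance for prescriptions/alert segments slightly outside the stay;
#: such boundary records are clipped downstream.
BOUNDARY_TOLERANCE = timedelta(days=1)


@dataclass(frozen=True)
class PatientCase:
    """One inpatient stay; its boundaries anchor the interval grid."""

    case_id: str
    admission_ts: datetime
    discharge_ts: datetime

    def __post_init__(self) -> None:
        if not self.admission_ts < self.discharge_ts:
            raise ValidationError(
                f"case {self.case_id}: admission_ts {self.admission_ts} must "
                f"precede discharge_ts {self.discharge_ts}"
            )


@dataclass(frozen=True)
class PrescriptionRecord:
    """A single prescription entry.

    Regimen changes are documented as separate entries, so one clinical
    course of therapy may appear as several records; the linkage module
    chains them back together.
    """

    rx_id: str
    case_id: str
    drug_code: str
    route: str
    schedule_kind: ScheduleKind
    start_ts: datetime
    end_ts: datetime

    def __post_init__(self) -> None:
        if self.start_ts > self.end_ts:
            raise ValidationError(
                f"prescription {self.rx_id}: start_ts after end_ts"
            )
        if self.start_ts == self.end_ts and self.schedule_kind is not ScheduleKind.ONE_TIME:
            raise ValidationError(
                f"prescription {self.rx_id}: zero-length span only permitted "
                f"for one_time prescriptions"
            )


def normalize_segments(
    segments: list[tuple[datetime, datetime]],
) -> list[tuple[datetime, datetime]]:
    """Sort display segments and merge overlapping or abutting ones.

    True gaps (positive time between consecutive segments) are preserved:
    whether a gap matters is decided by the interval engine, not here.
    """
    merged: list[tuple[datetime, datetime]] = []
    for start, end in sorted(segments):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class AlertRecord:
    """One alert, identified by a unique alert ID across all its displays.

    ``display_segments`` holds the on-screen periods; the export fragments
    these arbitrarily (e.g., ward-transfer pauses), so segments are
    normalized (sorted, overlaps/abutments merged) on construction.
    """

    alert_id: str
    case_id: str
    alert_type: AlertType
    severity: Severity
    interactive: bool
    trigger_rx_ids: frozenset[str]
    display_segments: list[tuple[datetime, datetime]]

    def __post_init__(self) -> None:
        if not self.trigger_rx_ids:
            raise ValidationError(f"alert {self.alert_id}: no triggering prescriptions")
        if not self.display_segments:
            raise ValidationError(f"alert {self.alert_id}: no display segments")
        for start, end in self.display_segments:
            if not start < end:
                raise ValidationError(
                    f"alert {self.alert_id}: display segment {start}..{end} "
                    f"must have positive duration"
                )
        self.display_segments = normalize_segments(self.display_segments)


@dataclass
class Dataset:
    """The three validated event collections of one export."""

    cases: list[PatientCase] = field(default_factory=list)
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    alerts: list[AlertRecord] = field(default_factory=list)

    def case_by_id(self) -> dict[str, PatientCase]:
        return {c.case_id: c for c in self.cases}

    def rx_by_id(self) -> dict[str, PrescriptionRecord]:
        return {p.rx_id: p for p in self.prescriptions}

    def validate(self) -> None:
        """Check uniqueness, referential integrity, and stay-boundary bounds."""
        cases = {}
        for c in self.cases:
            if c.case_id in cases:
                raise ValidationError(f"duplicate case_id {c.case_id}")
            cases[c.case_id] = c
        rxs = {}
        for p in self.prescriptions:
            if p.rx_id in rxs:
                raise ValidationError(f"duplicate rx_id {p.rx_id}")
            if p.case_id not in cases:
                raise IntegrityError(
                    f"prescription {p.rx_id} references unknown case {p.case_id}"
                )
            rxs[p.rx_id] = p
            case = cases[p.case_id]
            lo = case.admission_ts - BOUNDARY_TOLERANCE
            hi = case.discharge_ts + BOUNDARY_TOLERANCE
            if p.start_ts < lo or p.end_ts > hi:
                raise ValidationError(
                    f"prescription {p.rx_id} lies outside stay bounds of "
                    f"case {p.case_id} (±1 day tolerance)"
                )
        seen_alerts = set()
        for a in self.alerts:
            if a.alert_id in seen_alerts:
                raise ValidationError(f"duplicate alert_id {a.alert_id}")
            seen_alerts.add(a.alert_id)
            if a.case_id not in cases:
                raise IntegrityError(
                    f"alert {a.alert_id} references unknown case {a.case_id}"
                )
            for rx_id in a.trigger_rx_ids:
                if rx_id not in rxs:
                    raise IntegrityError(
                        f"alert {a.alert_id} references unknown rx_id {rx_id}"
                    )
                if rxs[rx_id].case_id != a.case_id:
                    raise IntegrityError(
                        f"alert {a.alert_id} (case {a.case_id}) triggered by "
                        f"prescription {rx_id} of a different case"
                    )
            case = cases[a.case_id]
            lo = case.admission_ts - BOUNDARY_TOLERANCE
            hi = case.discharge_ts + BOUNDARY_TOLERANCE
            for start, end in a.display_segments:
                if start < lo or end > hi:
                    raise ValidationError(
                        f"alert {a.alert_id} display segment outside stay "
                        f"bounds of case {a.case_id} (±1 day tolerance)"
                    )
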