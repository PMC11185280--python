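from __future__ import annotations

from dataclasses import replace
from datetime import datetime, timedelta

import numpy as np
import pytest

from alertraster.model import (
    AlertRecord,
    AlertType,
    Dataset,
    PatientCase,
    PrescriptionRecord,
    ScheduleKind,
    Severity,
)


def ts(s: str) -> datetime:
    return datetime.fromisoformat(s)


def make_alert(alert_id, case_id, triggers, segments, alert_type=AlertType.DDI,
               interactive=False, severity=Severity.MODERATE) -> AlertRecord:
    return AlertRecord(
        alert_id=alert_id, case_id=case_id, alert_type=alert_type,
        severity=severity, interactive=interactive,
        trigger_rx_ids=frozenset(triggers),
        display_segments=[(ts(a), ts(b)) for a, b in segments],
    )


def make_rx(rx_id, case_id, drug, start, end, route="PO",
            kind=ScheduleKind.REGULAR) -> PrescriptionRecord:
    return PrescriptionRecord(
        rx_id=rx_id, case_id=case_id, drug_code=drug, route=route,
        schedule_kind=kind, start_ts=ts(start), end_ts=ts(end),
    )


@pytest.fixture
def worked_example_dataset() -> Dataset:
    """A 5-day inpatient stay with four alerts.

    Alert W1 is displayed from admission (day 1) through day 4 while its
    prescription continues into day 5 (an absent alert, DDoA 4). Alert W2 is
    displayed from day 2 until discharge (persistent, DDoA 4). Alert W3 is
    displayed only on day 3 with its prescription continuing (absent,
    DDoA 1). Alert W4 first appears on the discharge day (excluded, DDoA 1).
    """
    case = PatientCase("CASE1", ts("2024-03-01T10:00"), ts("2024-03-05T12:00"))
    prescriptions = [
        make_rx("R1", "CASE1", "D1", "2024-03-01T10:30", "2024-03-05T11:00"),
        make_rx("R2", "CASE1", "D2", "2024-03-02T08:00", "2024-03-05T12:00"),
        make_rx("R3", "CASE1", "D3", "2024-03-03T06:00", "2024-03-04T18:00"),
        make_rx("R4", "CASE1", "D4", "2024-03-05T08:00", "2024-03-05T12:00"),
    ]
    alerts = [
        make_alert("W1", "CASE1", ["R1"], [("2024-03-01T10:40", "2024-03-04T20:00")]),
        make_alert("W2", "CASE1", ["R2"], [("2024-03-02T08:10", "2024-03-05T11:30")],
                   alert_type=AlertType.DAI),
        make_alert("W3", "CASE1", ["R3"], [("2024-03-03T06:10", "2024-03-03T20:00")],
                   alert_type=AlertType.PE_MDD),
        make_alert("W4", "CASE1", ["R4"], [("2024-03-05T08:10", "2024-03-05T11:00")],
                   alert_type=AlertType.DP),
    ]
    ds = Dataset(cases=[case], prescriptions=prescriptions, alerts=alerts)
    ds.validate()
    return ds


def inject_day_pauses(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Split alert display segments with short intra-day gaps.

    Each pause lies strictly inside one calendar day's portion of a segment
    and leaves positive display time in that day, mimicking ward-transfer
    display interruptions without changing any interval-level presence.
    """
    new_alerts = []
    for alert in dataset.alerts:
        segs = []
        for s, e in alert.display_segments:
            day_start = datetime.combine(s.date(), datetime.min.time())
            cut = False
            d = day_start
            while d < e and not cut:
                a = max(s, d)
                b = min(e, d + timedelta(days=1))
                if (b - a) >= timedelta(minutes=30) and rng.random() < 0.7:
                    m1 = a + timedelta(minutes=10)
                    m2 = m1 + timedelta(minutes=5)
                    segs.extend([(s, m1), (m2, e)])
                    cut = True
                d += timedelta(days=1)
            if not cut:
                segs.append((s, e))
        new_alerts.append(replace(alert, display_segments=segs))
    return Dataset(cases=dataset.cases, prescriptions=dataset.prescriptions,
                   alerts=new_alerts)
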