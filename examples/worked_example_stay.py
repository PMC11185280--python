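"""Classify four alerts over a single 5-day inpatient stay.

Builds a small event log in memory: a patient admitted on day 1 and
discharged on day 5, with four alerts whose display patterns cover the
canonical cases — disappearance during a continuing prescription (absent),
display until discharge (persistent), a one-day display (absent), and a
first display on the discharge day (excluded). Prints each alert's display
duration (DDoA, inclusive count of 24-hour intervals) and its label.
"""

from datetime import datetime

from alertraster import (
    AlertRecord, AlertType, Dataset, PatientCase, PrescriptionRecord,
    ScheduleKind, Severity, analyze_dataset,
)

ts = datetime.fromisoformat


def rx(rx_id, drug, start, end):
    return PrescriptionRecord(rx_id=rx_id, case_id="CASE1", drug_code=drug,
                              route="PO", schedule_kind=ScheduleKind.REGULAR,
                              start_ts=ts(start), end_ts=ts(end))


def alert(alert_id, atype, trigger, start, end):
    return AlertRecord(alert_id=alert_id, case_id="CASE1", alert_type=atype,
                       severity=Severity.MODERATE, interactive=False,
                       trigger_rx_ids=frozenset([trigger]),
                       display_segments=[(ts(start), ts(end))])


ds = Dataset(
    cases=[PatientCase("CASE1", ts("2024-03-01T10:00"), ts("2024-03-05T12:00"))],
    prescriptions=[
        rx("R1", "D1", "2024-03-01T10:30", "2024-03-05T11:00"),
        rx("R2", "D2", "2024-03-02T08:00", "2024-03-05T12:00"),
        rx("R3", "D3", "2024-03-03T06:00", "2024-03-04T18:00"),
        rx("R4", "D4", "2024-03-05T08:00", "2024-03-05T12:00"),
    ],
    alerts=[
        alert("A1", AlertType.DDI, "R1", "2024-03-01T10:40", "2024-03-04T20:00"),
        alert("A2", AlertType.DAI, "R2", "2024-03-02T08:10", "2024-03-05T11:30"),
        alert("A3", AlertType.PE_MDD, "R3", "2024-03-03T06:10", "2024-03-03T20:00"),
        alert("A4", AlertType.DP, "R4", "2024-03-05T08:10", "2024-03-05T11:00"),
    ],
)
ds.validate()

res = analyze_dataset(ds)
print("alert  days_displayed  ddoa  label")
for o in res.outcomes:
    days = f"{o.first_index}-{o.last_index}" if o.first_index != o.last_index else str(o.first_index)
    label = o.status.value if o.exclusion_reason.value == "none" else (
        f"excluded ({o.exclusion_reason.value})")
    print(f"{o.alert_id:<6} {days:<14} {o.ddoa_days:<5} {label}")

# A1 vanishes on day 5 while its prescription continues -> absent (a likely
# accepted alert). A2 runs to discharge -> persistent. A4 cannot be judged:
# there is no day-6 interval to compare against -> excluded.
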