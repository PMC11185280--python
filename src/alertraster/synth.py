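"""Synthetic CPOE event-log generator with ground-truth alert labels.

Emulates the statistical structure the event analysis consumes: longitudinal
inpatient stays (median length of stay 7 days), per-type alert streams with
realistic type shares, alerts triggered by one-time prescriptions (~16.3%),
alerts first displayed on the discharge day (~1.9%), follow-up prescription
chains realized as split prescriptions with small gaps, and intra-day
display pauses mimicking ward transfers. Every alert carries a truth label
(absent / persistent / excluded-with-reason) realized at interval
granularity: an absent alert's display stops at least one full interval
before its trigger chains end, so the label is unambiguous under the
24-hour rasterization. Sub-interval ambiguity is deliberately never
generated.

Clinical realism of drug choices, severities, or alert co-occurrence is not
attempted — only the structure the method measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from .classify import AlertOutcome, ExclusionReason, Status
from .io import write_dataset
from .model import (
    AlertRecord,
    AlertType,
    Dataset,
    IntegrityError,
    PatientCase,
    PrescriptionRecord,
    ScheduleKind,
    Severity,
)


class SynthConfigError(ValueError):
    """The requested configuration cannot be realized."""


# Per-case per-type expected alert counts. Shares follow the observed type
# mix of a large CPOE cohort (duplicate prescriptions dominate), scaled to
# ~8.4 alerts per case.
DEFAULT_ALERT_RATE: dict[AlertType, float] = {
    AlertType.DP: 5.60,
    AlertType.DDI: 1.73,
    AlertType.DAI: 0.38,
    AlertType.PIM: 0.37,
    AlertType.PE_MDD: 0.30,
}

# Probability that an analyzed alert resolves (disappears during a
# continuing prescription) rather than persisting, per alert type.
DEFAULT_P_ABSENT: dict[AlertType, float] = {
    AlertType.DP: 0.481,
    AlertType.DDI: 0.809,
    AlertType.DAI: 0.805,
    AlertType.PIM: 0.399,
    AlertType.PE_MDD: 0.519,
}

_NB_R = 1.2  # dispersion of the length-of-stay distribution (generator detail)


@dataclass(frozen=True)
class TruthLabel:
    status: Status
    exclusion_reason: ExclusionReason = ExclusionReason.NONE


@dataclass(frozen=True)
class SynthConfig:
    n_cases: int = 200
    los_median_days: int = 7
    alert_rate: Mapping[AlertType, float] = field(
        default_factory=lambda: dict(DEFAULT_ALERT_RATE)
    )
    p_absent: Mapping[AlertType, float] = field(
        default_factory=lambda: dict(DEFAULT_P_ABSENT)
    )
    #: geometric parameter for extra display days before resolution
    resolution_day_param: float = 0.45
    one_time_fraction: float = 0.163
    discharge_onset_fraction: float = 0.019
    interactive_fraction: float = 0.0
    #: expected intra-day display pauses per alert-day (ward transfers)
    pause_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise SynthConfigError("n_cases must be >= 0")
        if self.los_median_days < 1:
            raise SynthConfigError("los_median_days must be >= 1")
        fracs = (
            self.one_time_fraction, self.discharge_onset_fraction,
            self.interactive_fraction, self.resolution_day_param, self.pause_rate,
        )
        for f in fracs[:4]:
            if not 0 <= f <= 1:
                raise SynthConfigError("fractions/probabilities must lie in [0, 1]")
        if self.one_time_fraction + self.discharge_onset_fraction + self.interactive_fraction > 1:
            raise SynthConfigError("exclusion fractions sum above 1")
        if self.pause_rate < 0:
            raise SynthConfigError("pause_rate must be >= 0")
        for t, r in self.alert_rate.items():
            if r < 0:
                raise SynthConfigError(f"alert_rate[{t}] must be >= 0")
        for t, p in self.p_absent.items():
            if not 0 <= p <= 1:
                raise SynthConfigError(f"p_absent[{t}] must lie in [0, 1]")


def _nb_p_for_median(target_median: int, r: float = _NB_R) -> float:
    """Success probability p such that 1 + NegBin(r, p) has the target median.

    The median is a nonincreasing step function of p; the returned p sits at
    the center of the plateau where the median equals the target.
    """
    m = target_median - 1

    def median_at(p: float) -> int:
        return int(nbinom.ppf(0.5, r, p))

    def smallest_p_with_median_le(value: int) -> float:
        lo, hi = 1e-9, 1 - 1e-9
        for _ in range(80):
            mid = (lo + hi) / 2
            if median_at(mid) > value:
                lo = mid
            else:
                hi = mid
        return hi

    p1 = smallest_p_with_median_le(m)
    p2 = smallest_p_with_median_le(m - 1) if m >= 1 else 1 - 1e-9
    p = (p1 + p2) / 2
    if median_at(p) != m:
        raise SynthConfigError(
            f"cannot realize a length-of-stay median of {target_median} days"
        )
    return p


def _minutes(n: int) -> timedelta:
    return timedelta(minutes=int(n))


class _CaseFrame:
    """Interval geometry of one synthetic stay (calendar-day rasterization)."""

    def __init__(self, case: PatientCase):
        self.case = case
        last_day = (case.discharge_ts - timedelta(minutes=1)).date()
        self.n = (last_day - case.admission_ts.date()).days + 1

    def istart(self, i: int) -> datetime:
        if i == 1:
            return self.case.admission_ts
        return datetime.combine(
            self.case.admission_ts.date() + timedelta(days=i - 1), time.min
        )

    def iend(self, i: int) -> datetime:
        if i == self.n:
            return self.case.discharge_ts
        return datetime.combine(
            self.case.admission_ts.date() + timedelta(days=i), time.min
        )


def generate(config: SynthConfig) -> tuple[Dataset, dict[str, TruthLabel]]:
    """Draw a synthetic Dataset and the per-alert truth labels.

    Reproducible under a fixed seed: all randomness flows from one
    ``numpy.random.Generator``. Analyzed (non-excluded) alerts are placed
    only on stays spanning at least two intervals; if the configuration
    admits no such stay while analyzed alerts are drawn, a config error is
    raised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_nb = _nb_p_for_median(config.los_median_days)

    cases: list[PatientCase] = []
    frames: list[_CaseFrame] = []
    for i in range(config.n_cases):
        los = 1 + int(rng.negative_binomial(_NB_R, p_nb))
        base = date(2024, 1, 1) + timedelta(days=int(rng.integers(0, 300)))
        if los == 1:
            adm = datetime.combine(base, time(int(rng.integers(7, 11)), int(rng.integers(0, 60))))
            dis = datetime.combine(base, time(int(rng.integers(14, 19)), int(rng.integers(0, 60))))
        else:
            adm = datetime.combine(base, time(int(rng.integers(7, 21)), int(rng.integers(0, 60))))
            dis = datetime.combine(
                base + timedelta(days=los - 1),
                time(int(rng.integers(8, 18)), int(rng.integers(0, 60))),
            )
        case = PatientCase(case_id=f"C{i + 1:04d}", admission_ts=adm, discharge_ts=dis)
        cases.append(case)
        frames.append(_CaseFrame(case))

    eligible = [f for f in frames if f.n >= 2]

    prescriptions: list[PrescriptionRecord] = []
    alerts: list[AlertRecord] = []
    truth: dict[str, TruthLabel] = {}
    counters = {"rx": 0, "alert": 0, "drug": 0}

    def new_rx_id() -> str:
        counters["rx"] += 1
        return f"R{counters['rx']:06d}"

    def new_drug() -> str:
        counters["drug"] += 1
        return f"DRUG{counters['drug']:05d}"

    def emit_chain(
        frame: _CaseFrame, start: datetime, end: datetime, kind: ScheduleKind
    ) -> list[str]:
        """One continuous prescription, possibly split into two follow-up
        entries separated by a 5-minute gap."""
        drug = new_drug()
        route = "PO"
        ids = []
        if end - start > timedelta(hours=2) and rng.random() < 0.5:
            mid = start + _minutes(int((end - start).total_seconds() // 60 // 2))
            parts = [(start, mid), (mid + _minutes(5), end)]
        else:
            parts = [(start, end)]
        for s, e in parts:
            rx_id = new_rx_id()
            prescriptions.append(
                PrescriptionRecord(
                    rx_id=rx_id, case_id=frame.case.case_id, drug_code=drug,
                    route=route, schedule_kind=kind, start_ts=s, end_ts=e,
                )
            )
            ids.append(rx_id)
        return ids

    def daily_segments(frame: _CaseFrame, first: int, last: int,
                       last_end: datetime | None = None) -> list[tuple[datetime, datetime]]:
        """One display segment per interval in [first, last]; each stays
        strictly inside its interval so presence is exactly first..last."""
        segs = []
        for i in range(first, last + 1):
            s = frame.istart(i) + _minutes(int(rng.integers(25, 46)))
            if i == last and last_end is not None:
                e = last_end
            else:
                e = frame.iend(i) - _minutes(int(rng.integers(5, 31)))
            if s >= e:  # short admission/discharge interval: shrink margins
                s = frame.istart(i) + _minutes(5)
                e = (frame.iend(i) if last_end is None or i != last else last_end) - _minutes(5)
            segs.append((s, e))
        return segs

    def inject_pauses(segs: list[tuple[datetime, datetime]]) -> list[tuple[datetime, datetime]]:
        out = []
        for s, e in segs:
            span_min = int((e - s).total_seconds() // 60)
            if span_min >= 90 and rng.random() < config.pause_rate:
                m1 = s + _minutes(int(rng.integers(20, span_min // 2)))
                m2 = m1 + _minutes(int(rng.integers(10, 61)))
                if m2 < e - _minutes(5):
                    out.extend([(s, m1), (m2, e)])
                    continue
            out.append((s, e))
        return out

    def add_alert(frame: _CaseFrame, atype: AlertType, interactive: bool,
                  trigger_ids: list[str], segments: list[tuple[datetime, datetime]],
                  label: TruthLabel) -> None:
        counters["alert"] += 1
        alert_id = f"A{counters['alert']:06d}"
        severity = Severity(
            ["contraindicated", "severe", "moderate"][int(rng.integers(0, 3))]
        )
        alerts.append(
            AlertRecord(
                alert_id=alert_id, case_id=frame.case.case_id, alert_type=atype,
                severity=severity, interactive=interactive,
                trigger_rx_ids=frozenset(trigger_ids),
                display_segments=inject_pauses(segments),
            )
        )
        truth[alert_id] = label

    def make_one_time(frame: _CaseFrame, atype: AlertType) -> None:
        j = int(rng.integers(1, frame.n + 1))
        t0 = frame.istart(j) + _minutes(int(rng.integers(10, 40)))
        rx_id = new_rx_id()
        prescriptions.append(
            PrescriptionRecord(
                rx_id=rx_id, case_id=frame.case.case_id, drug_code=new_drug(),
                route="IV", schedule_kind=ScheduleKind.ONE_TIME, start_ts=t0, end_ts=t0,
            )
        )
        e = min(t0 + timedelta(hours=int(rng.integers(1, 4))), frame.iend(j) - _minutes(2))
        add_alert(frame, atype, False, [rx_id], [(t0, max(e, t0 + _minutes(5)))],
                  TruthLabel(Status.EXCLUDED, ExclusionReason.ONE_TIME_TRIGGER))

    def make_discharge_onset(frame: _CaseFrame, atype: AlertType) -> None:
        n = frame.n
        start = frame.istart(n) + _minutes(int(rng.integers(5, 25)))
        ids = emit_chain(frame, start, frame.case.discharge_ts, ScheduleKind.REGULAR)
        seg = (start + _minutes(5), frame.case.discharge_ts - _minutes(5))
        add_alert(frame, atype, False, ids, [seg],
                  TruthLabel(Status.EXCLUDED, ExclusionReason.DISCHARGE_DAY_FIRST_DISPLAY))

    def make_interactive(frame: _CaseFrame, atype: AlertType) -> None:
        f = int(rng.integers(1, frame.n + 1))
        start = frame.istart(f) + _minutes(int(rng.integers(2, 20)))
        ids = emit_chain(frame, start, frame.case.discharge_ts, ScheduleKind.REGULAR)
        add_alert(frame, atype, True, ids, daily_segments(frame, f, frame.n),
                  TruthLabel(Status.EXCLUDED, ExclusionReason.INTERACTIVE))

    def n_trigger_chains(atype: AlertType) -> int:
        return 2 if atype is AlertType.DP and rng.random() < 0.5 else 1

    def make_absent(frame: _CaseFrame, atype: AlertType) -> None:
        n = frame.n
        f = int(rng.integers(1, n))
        extra = int(rng.geometric(config.resolution_day_param)) - 1
        last = min(f + extra, n - 1)
        ids: list[str] = []
        for _ in range(n_trigger_chains(atype)):
            # chain stays active in the first display-free interval (last+1)
            start = frame.istart(f) + _minutes(int(rng.integers(2, 21)))
            after = frame.istart(last + 1)
            cap = frame.iend(last + 1) - _minutes(30)
            end = min(after + timedelta(hours=int(rng.integers(2, 8))), cap)
            kind = (ScheduleKind.AS_NEEDED
                    if atype is AlertType.DP and rng.random() < 0.3
                    else ScheduleKind.REGULAR)
            ids += emit_chain(frame, start, end, kind)
        add_alert(frame, atype, False, ids, daily_segments(frame, f, last),
                  TruthLabel(Status.ABSENT))

    def make_persistent(frame: _CaseFrame, atype: AlertType) -> None:
        n = frame.n
        f = int(rng.integers(1, n))
        if rng.random() < 0.5:
            # displayed until discharge; prescription runs to discharge
            ids: list[str] = []
            for _ in range(n_trigger_chains(atype)):
                start = frame.istart(f) + _minutes(int(rng.integers(2, 21)))
                ids += emit_chain(frame, start, frame.case.discharge_ts, ScheduleKind.REGULAR)
            add_alert(frame, atype, False, ids, daily_segments(frame, f, n),
                      TruthLabel(Status.PERSISTENT))
        else:
            # prescription (and display) end mid-stay: disappearance coincides
            # with end of every triggering chain
            extra = int(rng.geometric(config.resolution_day_param)) - 1
            last = min(f + extra, n - 1)
            dur_min = int((frame.iend(last) - frame.istart(last)).total_seconds() // 60)
            back = min(int(rng.integers(60, 181)), dur_min // 2)
            t_end = frame.iend(last) - _minutes(back)
            ids = []
            for _ in range(n_trigger_chains(atype)):
                start = frame.istart(f) + _minutes(int(rng.integers(2, 21)))
                ids += emit_chain(frame, start, t_end, ScheduleKind.REGULAR)
            segs = daily_segments(frame, f, last, last_end=t_end - _minutes(5))
            add_alert(frame, atype, False, ids, segs, TruthLabel(Status.PERSISTENT))

    thresholds = np.cumsum([
        config.one_time_fraction, config.discharge_onset_fraction,
        config.interactive_fraction,
    ])
    for frame in frames:
        for atype, rate in config.alert_rate.items():
            for _ in range(int(rng.poisson(rate))):
                u = rng.random()
                if u < thresholds[0]:
                    make_one_time(frame, atype)
                elif u < thresholds[1]:
                    make_discharge_onset(frame, atype)
                elif u < thresholds[2]:
                    make_interactive(frame, atype)
                else:
                    target = frame
                    if target.n < 2:
                        if not eligible:
                            raise SynthConfigError(
                                "analyzed alerts require a stay of >= 2 intervals, "
                                "but every generated stay spans a single day"
                            )
                        target = eligible[int(rng.integers(0, len(eligible)))]
                    if rng.random() < config.p_absent.get(atype, 0.0):
                        make_absent(target, atype)
                    else:
                        make_persistent(target, atype)

    dataset = Dataset(cases=cases, prescriptions=prescriptions, alerts=alerts)
    dataset.validate()
    return dataset, truth


def write_truth(truth: dict[str, TruthLabel], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {"alert_id": aid, "truth_status": lab.status.value,
             "truth_exclusion_reason": lab.exclusion_reason.value}
            for aid, lab in sorted(truth.items())
        ],
        columns=["alert_id", "truth_status", "truth_exclusion_reason"],
    )
    path = out / "truth.csv"
    df.to_csv(path, index=False)
    return path


def simulate_to_dir(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the three input CSVs plus truth.csv."""
    dataset, truth = generate(config)
    manifest = write_dataset(dataset, out_dir)
    manifest["truth"] = write_truth(truth, out_dir)
    return manifest


@dataclass
class RecoveryReport:
    """Agreement between generator truth and engine outcomes."""

    confusion: pd.DataFrame  # truth label x assigned label counts
    agreement: float
    n: int


def truth_recovery_report(
    truth: dict[str, TruthLabel], outcomes: list[AlertOutcome]
) -> RecoveryReport:
    """Confusion counts of truth vs engine labels; exact-label agreement.

    Excluded alerts agree only if the exclusion reason matches too.
    """
    if not truth and not outcomes:
        return RecoveryReport(
            confusion=pd.DataFrame(columns=["truth", "assigned", "count"]),
            agreement=float("nan"), n=0,
        )
    by_id = {o.alert_id: o for o in outcomes}
    if set(by_id) != set(truth):
        missing = set(truth) ^ set(by_id)
        raise IntegrityError(
            f"truth and outcomes cover different alerts ({len(missing)} mismatched)"
        )

    def key(status: Status, reason: ExclusionReason) -> str:
        if status is Status.EXCLUDED:
            return f"excluded:{reason.value}"
        return status.value

    pairs = [
        (key(truth[aid].status, truth[aid].exclusion_reason),
         key(o.status, o.exclusion_reason))
        for aid, o in sorted(by_id.items())
    ]
    df = (
        pd.DataFrame(pairs, columns=["truth", "assigned"])
        .value_counts()
        .reset_index(name="count")
        .sort_values(["truth", "assigned"])
        .reset_index(drop=True)
    )
    agree = sum(t == a for t, a in pairs) / len(pairs)
    return RecoveryReport(confusion=df, agreement=agree, n=len(pairs))
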