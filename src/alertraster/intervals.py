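"""Rasterization of inpatient stays into midnight-anchored day intervals.

Every stay is tiled with half-open intervals ``[start, end)``. With the
default 24-hour width the intervals are calendar days: the first runs from
admission to the next midnight, the last from the final midnight to
discharge, so first and last intervals may be shorter than 24 h. Per
interval, the engine records which alerts were on display and which
prescription chains were active — presence requires strictly positive
overlap, which is what absorbs intra-day display pauses (ward transfers)
without masquerading as alert disappearance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Iterable

from .linkage import PrescriptionChain, chain_active_in
from .model import AlertRecord, PatientCase

logger = logging.getLogger(__name__)


class AlertNotDisplayedError(KeyError):
    """The queried alert appears in no interval of the grid."""


@dataclass
class DayInterval:
    index: int  # 1-based ordinal within the stay
    start_ts: datetime
    end_ts: datetime
    displayed_alert_ids: set[str] = field(default_factory=set)
    active_chain_ids: set[str] = field(default_factory=set)


@dataclass
class IntervalGrid:
    case_id: str
    intervals: list[DayInterval]

    def presence_indices(self, alert_id: str) -> list[int]:
        return [iv.index for iv in self.intervals if alert_id in iv.displayed_alert_ids]


def _interval_bounds(
    case: PatientCase, interval_hours: float
) -> list[tuple[datetime, datetime]]:
    """Half-open interval boundaries tiling [admission, discharge).

    Boundaries sit at ``admission-day midnight + k * interval_hours``; with
    the 24 h default this is exactly the calendar-day (each-midnight) grid.
    """
    if interval_hours <= 0:
        raise ValueError("interval_hours must be positive")
    step = timedelta(hours=interval_hours)
    anchor = datetime.combine(case.admission_ts.date(), time.min)
    bounds = []
    k = (case.admission_ts - anchor) // step
    cursor = anchor + k * step
    while cursor < case.discharge_ts:
        start = max(cursor, case.admission_ts)
        end = min(cursor + step, case.discharge_ts)
        if start < end:
            bounds.append((start, end))
        cursor += step
    return bounds


def _overlaps(
    segments: Iterable[tuple[datetime, datetime]], start: datetime, end: datetime
) -> bool:
    return any(max(s, start) < min(e, end) for s, e in segments)


def build_grid(
    case: PatientCase,
    alerts: Iterable[AlertRecord],
    chains: Iterable[PrescriptionChain],
    interval_hours: float = 24.0,
) -> IntervalGrid:
    """Rasterize one case: per interval, the displayed alerts and active chains.

    Alert segments are clipped to the stay; a segment lying entirely outside
    it is dropped with a logged warning. Presence in an interval requires
    strictly positive overlap, so refragmenting segments within a day never
    changes the result.
    """
    bounds = _interval_bounds(case, interval_hours)
    grid = IntervalGrid(
        case_id=case.case_id,
        intervals=[
            DayInterval(index=i, start_ts=s, end_ts=e)
            for i, (s, e) in enumerate(bounds, start=1)
        ],
    )
    for alert in alerts:
        if alert.case_id != case.case_id:
            raise ValueError(f"alert {alert.alert_id} does not belong to case {case.case_id}")
        clipped = [
            (max(s, case.admission_ts), min(e, case.discharge_ts))
            for s, e in alert.display_segments
        ]
        kept = [(s, e) for s, e in clipped if s < e]
        if len(kept) < len(clipped):
            logger.warning(
                "alert %s: %d display segment(s) outside stay %s dropped after clipping",
                alert.alert_id, len(clipped) - len(kept), case.case_id,
            )
        for iv in grid.intervals:
            if _overlaps(kept, iv.start_ts, iv.end_ts):
                iv.displayed_alert_ids.add(alert.alert_id)
    for chain in chains:
        if chain.case_id != case.case_id:
            raise ValueError(f"chain {chain.chain_id} does not belong to case {case.case_id}")
        for iv in grid.intervals:
            if chain_active_in(chain, iv.start_ts, iv.end_ts):
                iv.active_chain_ids.add(chain.chain_id)
    return grid


def presence_profile(grid: IntervalGrid, alert_id: str) -> tuple[int, int, set[int]]:
    """(first_index, last_index, gap_indices) for one alert's display run.

    ``gap_indices`` are intervals strictly between first and last in which
    the alert was not displayed.
    """
    present = grid.presence_indices(alert_id)
    if not present:
        raise AlertNotDisplayedError(
            f"alert {alert_id} displayed in no interval of case {grid.case_id}"
        )
    first, last = present[0], present[-1]
    gaps = set(range(first + 1, last)) - set(present)
    return first, last, gaps
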