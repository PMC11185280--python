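"""Exclusion rules and absent/persistent classification of alerts.

An alert is "absent" when it stops being displayed in a subsequent 24-hour
interval although its triggering prescription continues — the event-analysis
proxy for the alert having been acted on. It is "persistent" when it is
displayed in every consecutive interval until discharge or until its
prescription ends. Three kinds of alerts cannot be evaluated and are
excluded up front: alerts triggered by one-time prescriptions (no next-day
comparison possible), alerts that require user interaction to resolve their
conditions, and alerts first displayed on the discharge day (no subsequent
interval exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .intervals import AlertNotDisplayedError, IntervalGrid, presence_profile
from .linkage import PrescriptionChain, chain_active_in, chains_for_alert
from .model import AlertRecord, AlertType, Dataset, ScheduleKind

logger = logging.getLogger(__name__)


class Status(str, Enum):
    PERSISTENT = "persistent"
    ABSENT = "absent"
    EXCLUDED = "excluded"


class ExclusionReason(str, Enum):
    NONE = "none"
    ONE_TIME_TRIGGER = "one_time_trigger"
    INTERACTIVE = "interactive"
    DISCHARGE_DAY_FIRST_DISPLAY = "discharge_day_first_display"


class ContinuityRule(str, Enum):
    """How 'the prescription continues' is judged for multi-trigger alerts.

    any_chain_active: absent if at least one triggering chain is still
    active in the first display-free interval (default — a resolved alert
    with a surviving, e.g. dose-reduced, prescription counts as absent).
    all_chains_active: absent only if every triggering chain is still active.
    stay_only: disappearance before discharge always counts as absent.
    """

    ANY_CHAIN_ACTIVE = "any_chain_active"
    ALL_CHAINS_ACTIVE = "all_chains_active"
    STAY_ONLY = "stay_only"


@dataclass(frozen=True)
class ClassificationPolicy:
    continuity_rule: ContinuityRule = ContinuityRule.ANY_CHAIN_ACTIVE
    interval_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.interval_hours <= 0:
            raise ValueError("interval_hours must be positive")


@dataclass(frozen=True)
class AlertOutcome:
    alert_id: str
    case_id: str
    alert_type: AlertType
    status: Status
    exclusion_reason: ExclusionReason
    first_index: int
    last_index: int
    ddoa_days: int
    absence_index: int | None = None  # first display-free interval (absent only)


def compute_ddoa(first_index: int, last_index: int) -> int:
    """Display duration of alerts: inclusive interval count between the
    first and last display."""
    if not 1 <= first_index <= last_index:
        raise ValueError(
            f"need 1 <= first_index <= last_index, got ({first_index}, {last_index})"
        )
    return last_index - first_index + 1


def _display_run(grid: IntervalGrid, alert_id: str) -> tuple[int, int]:
    """First index and end of the first contiguous display run.

    Absence is terminal: if the same alert ID reappears after a full
    display-free interval, classification happens at the first
    disappearance and the reappearance is logged as an anomaly.
    """
    first, last, gaps = presence_profile(grid, alert_id)
    if not gaps:
        return first, last
    run_end = first
    present = set(grid.presence_indices(alert_id))
    while run_end + 1 in present:
        run_end += 1
    logger.warning(
        "alert %s reappears after a display-free interval (gaps %s); "
        "classified at first disappearance",
        alert_id, sorted(gaps),
    )
    return first, run_end


def apply_exclusions(
    dataset: Dataset, grids: dict[str, IntervalGrid]
) -> tuple[list[AlertRecord], list[AlertOutcome]]:
    """Split alerts into analyzed ones and excluded outcomes.

    Rules are evaluated in fixed order per alert — one-time trigger, then
    interactive, then first display on the discharge day — and the first
    match is recorded.
    """
    rx_by_id = dataset.rx_by_id()
    analyzed: list[AlertRecord] = []
    excluded: list[AlertOutcome] = []
    for alert in dataset.alerts:
        grid = grids[alert.case_id]
        try:
            first, run_end = _display_run(grid, alert.alert_id)
        except AlertNotDisplayedError:
            # e.g. every segment clipped away as pre-admission
            logger.warning(
                "alert %s has no display within the stay; dropped", alert.alert_id
            )
            continue
        reason = ExclusionReason.NONE
        if any(
            rx_by_id[rx_id].schedule_kind is ScheduleKind.ONE_TIME
            for rx_id in sorted(alert.trigger_rx_ids)
        ):
            reason = ExclusionReason.ONE_TIME_TRIGGER
        elif alert.interactive:
            reason = ExclusionReason.INTERACTIVE
        elif first == len(grid.intervals):
            reason = ExclusionReason.DISCHARGE_DAY_FIRST_DISPLAY
        if reason is ExclusionReason.NONE:
            analyzed.append(alert)
        else:
            excluded.append(
                AlertOutcome(
                    alert_id=alert.alert_id,
                    case_id=alert.case_id,
                    alert_type=alert.alert_type,
                    status=Status.EXCLUDED,
                    exclusion_reason=reason,
                    first_index=first,
                    last_index=run_end,
                    ddoa_days=compute_ddoa(first, run_end),
                )
            )
    return analyzed, excluded


def classify_alert(
    grid: IntervalGrid,
    chains: Iterable[PrescriptionChain],
    alert: AlertRecord,
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> AlertOutcome:
    """Label one analyzed alert persistent or absent.

    Let k be the last interval of the alert's first contiguous display run.
    If k is the stay's final interval the alert is persistent. Otherwise
    interval k+1 is examined: under the default rule the alert is absent iff
    at least one triggering chain is still active there — a disappearance
    that coincides with the end of every triggering prescription is
    persistent, not absent.
    """
    first, run_end = _display_run(grid, alert.alert_id)
    ddoa = compute_ddoa(first, run_end)
    n_intervals = len(grid.intervals)
    common = dict(
        alert_id=alert.alert_id,
        case_id=alert.case_id,
        alert_type=alert.alert_type,
        first_index=first,
        last_index=run_end,
        ddoa_days=ddoa,
    )
    if run_end == n_intervals:
        return AlertOutcome(
            status=Status.PERSISTENT, exclusion_reason=ExclusionReason.NONE, **common
        )
    nxt = grid.intervals[run_end]  # 0-based list: interval with index run_end+1
    trigger_chains = chains_for_alert(chains, alert.trigger_rx_ids)
    active = [
        c for c in trigger_chains if chain_active_in(c, nxt.start_ts, nxt.end_ts)
    ]
    rule = policy.continuity_rule
    if rule is ContinuityRule.ANY_CHAIN_ACTIVE:
        absent = len(active) >= 1
    elif rule is ContinuityRule.ALL_CHAINS_ACTIVE:
        absent = bool(trigger_chains) and len(active) == len(trigger_chains)
    else:  # STAY_ONLY
        absent = True
    if absent:
        return AlertOutcome(
            status=Status.ABSENT,
            exclusion_reason=ExclusionReason.NONE,
            absence_index=run_end + 1,
            **common,
        )
    return AlertOutcome(
        status=Status.PERSISTENT, exclusion_reason=ExclusionReason.NONE, **common
    )


def classify_dataset(
    dataset: Dataset,
    grids: dict[str, IntervalGrid],
    chains: Iterable[PrescriptionChain],
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> list[AlertOutcome]:
    """Exclusions plus classification for every alert of a dataset."""
    chains = list(chains)
    chains_by_case: dict[str, list[PrescriptionChain]] = {}
    for c in chains:
        chains_by_case.setdefault(c.case_id, []).append(c)
    analyzed, excluded = apply_exclusions(dataset, grids)
    outcomes = list(excluded)
    for alert in analyzed:
        outcomes.append(
            classify_alert(
                grids[alert.case_id],
                chains_by_case.get(alert.case_id, []),
                alert,
                policy,
            )
        )
    outcomes.sort(key=lambda o: o.alert_id)
    return outcomes
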