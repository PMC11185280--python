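"""Chaining of follow-up prescriptions into continuous-prescription units.

A follow-up prescription is one of the same drug and administration route
that starts within a short window (default 10 minutes) of the previous
prescription's end — the pattern a regimen change leaves in an export where
every change is a new entry. Chains of follow-ups form the "continuous
prescriptions" against which alert disappearance is judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable

from .model import PrescriptionRecord

DEFAULT_LINKAGE_WINDOW = timedelta(minutes=10)


@dataclass
class PrescriptionChain:
    """An ordered run of follow-up-linked prescriptions.

    ``coverage`` is the chain's active time: member spans with inter-member
    gaps at or below the linkage window bridged into one span. Spans are
    disjoint and sorted.
    """

    chain_id: str
    case_id: str
    drug_code: str
    route: str
    member_rx_ids: list[str]
    coverage: list[tuple[datetime, datetime]]


def build_chains(
    prescriptions: Iterable[PrescriptionRecord],
    linkage_window: timedelta = DEFAULT_LINKAGE_WINDOW,
) -> list[PrescriptionChain]:
    """Partition prescriptions into maximal follow-up chains.

    Greedy in time order: within each (case, drug, route) group,
    prescriptions are processed by ascending start time and attached to an
    open chain when the gap from that chain's end lies in
    ``[0, linkage_window]`` (window inclusive). When several open chains
    qualify, the earliest-ending one is continued, which pairs each ending
    prescription with its earliest-starting follow-up candidate.
    Overlapping prescriptions of the same drug/route (duplicate therapy)
    are never chained: an overlap is not a follow-up. Deterministic under
    input shuffling (ties broken by start, end, then rx_id).
    """
    if linkage_window < timedelta(0):
        raise ValueError("linkage_window must be non-negative")

    groups: dict[tuple[str, str, str], list[PrescriptionRecord]] = {}
    for rx in prescriptions:
        groups.setdefault((rx.case_id, rx.drug_code, rx.route), []).append(rx)

    chains: list[PrescriptionChain] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: (r.start_ts, r.end_ts, r.rx_id))
        # open chains as lists of member records; last member's end defines the gap
        open_chains: list[list[PrescriptionRecord]] = []
        for rx in members:
            candidates = [
                ch
                for ch in open_chains
                if timedelta(0) <= rx.start_ts - ch[-1].end_ts <= linkage_window
            ]
            if candidates:
                target = min(candidates, key=lambda ch: (ch[-1].end_ts, ch[-1].rx_id))
                target.append(rx)
            else:
                open_chains.append([rx])
        for ch in open_chains:
            coverage: list[tuple[datetime, datetime]] = []
            for rx in ch:
                if coverage and rx.start_ts - coverage[-1][1] <= linkage_window:
                    coverage[-1] = (coverage[-1][0], max(coverage[-1][1], rx.end_ts))
                else:
                    coverage.append((rx.start_ts, rx.end_ts))
            chains.append(
                PrescriptionChain(
                    chain_id="",  # assigned below, after deterministic ordering
                    case_id=key[0],
                    drug_code=key[1],
                    route=key[2],
                    member_rx_ids=[rx.rx_id for rx in ch],
                    coverage=coverage,
                )
            )

    chains.sort(key=lambda c: (c.case_id, c.coverage[0][0], c.member_rx_ids[0]))
    for i, chain in enumerate(chains, start=1):
        chain.chain_id = f"CH{i:06d}"
    return chains


def chain_active_in(
    chain: PrescriptionChain, interval_start: datetime, interval_end: datetime
) -> bool:
    """True iff some coverage span overlaps ``[interval_start, interval_end)``
    with strictly positive duration."""
    if not interval_start < interval_end:
        raise ValueError("interval_start must precede interval_end")
    return any(
        max(start, interval_start) < min(end, interval_end)
        for start, end in chain.coverage
    )


def chains_for_alert(
    chains: Iterable[PrescriptionChain], trigger_rx_ids: frozenset[str]
) -> list[PrescriptionChain]:
    """The chains containing any of an alert's triggering prescriptions."""
    return [c for c in chains if trigger_rx_ids.intersection(c.member_rx_ids)]
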