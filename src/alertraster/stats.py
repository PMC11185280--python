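"""Summary tables, pairwise chi-square tests, and discrete time-to-event curves.

Works on classified alert outcomes. The summary table mirrors the usual
reporting layout: one row per alert type plus a TOTAL row, with triggered
counts (percent of the analyzed grand total), absent counts (percent within
type), and display-duration summaries (median, quartiles, range, in days).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .classify import AlertOutcome, Status
from .model import AlertType

TYPE_ORDER = [t.value for t in AlertType]
TOTAL = "TOTAL"

SUMMARY_COLUMNS = [
    "alert_type", "n_triggered", "pct_of_total", "n_absent", "pct_absent",
    "ddoa_median", "ddoa_q1", "ddoa_q3", "ddoa_min", "ddoa_max",
]


def _analyzed(outcomes: Iterable[AlertOutcome]) -> list[AlertOutcome]:
    return [o for o in outcomes if o.status is not Status.EXCLUDED]


def exclusion_accounting(outcomes: Iterable[AlertOutcome]) -> dict[str, float]:
    """Counts of total/excluded-by-reason/analyzed alerts and the analyzed share (%)."""
    outcomes = list(outcomes)
    counts: dict[str, float] = {"total": len(outcomes)}
    for o in outcomes:
        if o.status is Status.EXCLUDED:
            key = f"excluded_{o.exclusion_reason.value}"
            counts[key] = counts.get(key, 0) + 1
    analyzed = len(_analyzed(outcomes))
    counts["analyzed"] = analyzed
    counts["pct_analyzed"] = 100.0 * analyzed / len(outcomes) if outcomes else float("nan")
    return counts


def _ddoa_summary(ddoas: Sequence[int]) -> dict[str, float]:
    if not ddoas:
        return {k: np.nan for k in ("ddoa_median", "ddoa_q1", "ddoa_q3", "ddoa_min", "ddoa_max")}
    arr = np.asarray(ddoas, dtype=float)
    # quartiles by linear interpolation between order statistics
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "ddoa_median": med,
        "ddoa_q1": q1,
        "ddoa_q3": q3,
        "ddoa_min": float(arr.min()),
        "ddoa_max": float(arr.max()),
    }


def summarize_by_type(outcomes: Iterable[AlertOutcome]) -> pd.DataFrame:
    """Per-type summary plus a TOTAL row; excluded alerts are ignored.

    Triggered percentages are of the grand total of analyzed alerts;
    absence percentages are within each type.
    """
    analyzed = _analyzed(outcomes)
    grand_total = len(analyzed)
    rows = []
    types_present = [t for t in TYPE_ORDER if any(o.alert_type.value == t for o in analyzed)]
    for t in types_present + [TOTAL]:
        if t == TOTAL:
            sub = analyzed
        else:
            sub = [o for o in analyzed if o.alert_type.value == t]
        n = len(sub)
        n_absent = sum(o.status is Status.ABSENT for o in sub)
        rows.append({
            "alert_type": t,
            "n_triggered": n,
            "pct_of_total": 100.0 * n / grand_total if grand_total else np.nan,
            "n_absent": n_absent,
            "pct_absent": 100.0 * n_absent / n if n else np.nan,
            **_ddoa_summary([o.ddoa_days for o in sub]),
        })
    if not analyzed:
        # table of zero counts for every known type
        rows = [{
            "alert_type": t, "n_triggered": 0, "pct_of_total": np.nan,
            "n_absent": 0, "pct_absent": np.nan, **_ddoa_summary([]),
        } for t in TYPE_ORDER + [TOTAL]]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], no continuity
    correction; returns (statistic, two-tailed p, degenerate flag).

    A zero margin makes the test undefined; the degenerate flag is set and
    p reported as 1.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), False


def pairwise_chi2(summary: pd.DataFrame) -> pd.DataFrame:
    """Chi-square comparisons of absence rates for all unordered type pairs.

    Each 2x2 table is (absent, persistent) x (type_a, type_b); df = 1;
    p-values are two-tailed and unadjusted.
    """
    rows = []
    per_type = summary[summary["alert_type"] != TOTAL]
    for (_, ra), (_, rb) in combinations(per_type.iterrows(), 2):
        stat, p, degenerate = chi2_2x2(
            int(ra["n_absent"]), int(ra["n_triggered"] - ra["n_absent"]),
            int(rb["n_absent"]), int(rb["n_triggered"] - rb["n_absent"]),
        )
        rows.append({
            "type_a": ra["alert_type"], "type_b": rb["alert_type"],
            "chi2": stat, "df": 1, "p": p, "degenerate": degenerate,
        })
    return pd.DataFrame(rows, columns=["type_a", "type_b", "chi2", "df", "p", "degenerate"])


def time_to_absence_curves(
    outcomes: Iterable[AlertOutcome], max_day: int | None = None
) -> pd.DataFrame:
    """Discrete time-to-event proportions per alert type and day.

    For day t: ``prop_absent_by_day`` is the fraction of the type's analyzed
    alerts detected absent within t intervals of first display
    (absence_index - first_index <= t); ``prop_persistent_displayed`` is the
    fraction persistent with a display duration of at least t days. Simple
    proportions, not censoring-adjusted.
    """
    analyzed = _analyzed(outcomes)
    if max_day is None:
        horizons = [o.ddoa_days for o in analyzed]
        horizons += [o.absence_index - o.first_index for o in analyzed if o.absence_index]
        max_day = max(horizons, default=1)
    rows = []
    for t_enum in AlertType:
        t = t_enum.value
        sub = [o for o in analyzed if o.alert_type.value == t]
        if not sub:
            continue
        n = len(sub)
        for day in range(1, max_day + 1):
            n_abs = sum(
                o.status is Status.ABSENT and (o.absence_index - o.first_index) <= day
                for o in sub
            )
            n_pers = sum(
                o.status is Status.PERSISTENT and o.ddoa_days >= day for o in sub
            )
            rows.append({
                "alert_type": t, "day": day,
                "prop_absent_by_day": n_abs / n,
                "prop_persistent_displayed": n_pers / n,
            })
    return pd.DataFrame(
        rows, columns=["alert_type", "day", "prop_absent_by_day", "prop_persistent_displayed"]
    )
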