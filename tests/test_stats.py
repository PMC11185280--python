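from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alertraster.classify import AlertOutcome, ExclusionReason, Status
from alertraster.model import AlertType
from alertraster.stats import (
    chi2_2x2,
    exclusion_accounting,
    pairwise_chi2,
    summarize_by_type,
    time_to_absence_curves,
)


def outcome(i, atype=AlertType.DDI, status=Status.ABSENT, first=1, last=1,
            reason=ExclusionReason.NONE):
    return AlertOutcome(
        alert_id=f"A{i}", case_id="C1", alert_type=atype, status=status,
        exclusion_reason=reason, first_index=first, last_index=last,
        ddoa_days=last - first + 1,
        absence_index=last + 1 if status is Status.ABSENT else None,
    )


def outcomes_with_counts(counts):
    """counts: {type: (n_analyzed, n_absent)} with unit display durations."""
    outs, i = [], 0
    for atype, (n, n_abs) in counts.items():
        for j in range(n):
            status = Status.ABSENT if j < n_abs else Status.PERSISTENT
            outs.append(outcome(i, atype, status))
            i += 1
    return outs


class TestSummarize:
    def test_half_absent_is_fifty_percent(self):
        outs = outcomes_with_counts({AlertType.DDI: (10, 5)})
        row = summarize_by_type(outs).set_index("alert_type").loc["DDI"]
        assert row["pct_absent"] == 50.0

    def test_odd_length_median(self):
        outs = [outcome(i, last=d) for i, d in enumerate([1, 2, 2, 3, 10])]
        row = summarize_by_type(outs).set_index("alert_type").loc["DDI"]
        assert row["ddoa_median"] == 2
        assert row["ddoa_min"] == 1 and row["ddoa_max"] == 10

    def test_total_row_sums_types(self):
        outs = outcomes_with_counts({
            AlertType.DDI: (10, 5), AlertType.DP: (20, 4), AlertType.PIM: (5, 1),
        })
        df = summarize_by_type(outs).set_index("alert_type")
        per_type = df.drop(index="TOTAL")
        assert per_type["n_triggered"].sum() == df.loc["TOTAL", "n_triggered"]
        assert per_type["n_absent"].sum() == df.loc["TOTAL", "n_absent"]
        assert per_type["pct_of_total"].sum() == pytest.approx(100.0)

    def test_excluded_outcomes_ignored(self):
        outs = outcomes_with_counts({AlertType.DDI: (4, 2)})
        outs.append(outcome(99, status=Status.EXCLUDED,
                            reason=ExclusionReason.ONE_TIME_TRIGGER))
        df = summarize_by_type(outs).set_index("alert_type")
        assert df.loc["TOTAL", "n_triggered"] == 4


class TestExclusionAccounting:
    def test_counts_and_share(self):
        outs = outcomes_with_counts({AlertType.DDI: (6, 3)})
        outs.append(outcome(90, status=Status.EXCLUDED,
                            reason=ExclusionReason.ONE_TIME_TRIGGER))
        outs.append(outcome(91, status=Status.EXCLUDED,
                            reason=ExclusionReason.DISCHARGE_DAY_FIRST_DISPLAY))
        acc = exclusion_accounting(outs)
        assert acc["total"] == 8
        assert acc["excluded_one_time_trigger"] == 1
        assert acc["analyzed"] == 6
        assert acc["pct_analyzed"] == pytest.approx(75.0)


class TestChi2:
    def test_identical_rates_give_zero_statistic(self):
        stat, p, degenerate = chi2_2x2(10, 10, 10, 10)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not degenerate

    def test_zero_margin_flagged_degenerate(self):
        stat, p, degenerate = chi2_2x2(5, 0, 3, 0)
        assert degenerate and p == 1.0

    @given(
        st.tuples(*[st.integers(min_value=0, max_value=500) for _ in range(4)])
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_closed_form_pearson(self, cells):
        a, b, c, d = cells
        stat, p, degenerate = chi2_2x2(a, b, c, d)
        n = a + b + c + d
        margins = [(a + b), (c + d), (a + c), (b + d)]
        if n == 0 or 0 in margins:
            assert degenerate
            return
        expected = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
        assert stat == pytest.approx(expected, abs=1e-9, rel=1e-9)

    def test_pairwise_symmetric_and_complete(self):
        outs = outcomes_with_counts({
            AlertType.DP: (40, 10), AlertType.DDI: (30, 20), AlertType.DAI: (10, 8),
            AlertType.PIM: (12, 5), AlertType.PE_MDD: (9, 4),
        })
        tests = pairwise_chi2(summarize_by_type(outs))
        assert len(tests) == 10
        # symmetry: recompute with the pair swapped
        for _, row in tests.iterrows():
            s1, p1, _ = chi2_2x2(20, 10, 8, 2)
            s2, p2, _ = chi2_2x2(8, 2, 20, 10)
            assert p1 == pytest.approx(p2)
        assert (tests["df"] == 1).all()
        assert tests["p"].between(0, 1).all()


def brute_force_curves(outcomes, max_day):
    rows = []
    analyzed = [o for o in outcomes if o.status is not Status.EXCLUDED]
    for t in AlertType:
        sub = [o for o in analyzed if o.alert_type is t]
        if not sub:
            continue
        for day in range(1, max_day + 1):
            na = 0
            npers = 0
            for o in sub:
                if o.status is Status.ABSENT and o.absence_index - o.first_index <= day:
                    na += 1
                if o.status is Status.PERSISTENT and o.ddoa_days >= day:
                    npers += 1
            rows.append((t.value, day, na / len(sub), npers / len(sub)))
    return rows


class TestCurves:
    def test_all_absent_after_first_interval_peaks_at_day_one(self):
        outs = [outcome(i) for i in range(5)]
        df = time_to_absence_curves(outs, max_day=3)
        assert (df[df["day"] == 1]["prop_absent_by_day"] == 1.0).all()

    def test_no_absent_alerts_give_zero_curve(self):
        outs = [outcome(i, status=Status.PERSISTENT, last=3) for i in range(5)]
        df = time_to_absence_curves(outs, max_day=4)
        assert (df["prop_absent_by_day"] == 0.0).all()

    def test_matches_brute_force_recount_on_random_outcomes(self):
        rng = np.random.default_rng(12)
        outs = []
        for i in range(300):
            atype = list(AlertType)[int(rng.integers(0, 5))]
            first = int(rng.integers(1, 5))
            last = first + int(rng.integers(0, 6))
            status = [Status.ABSENT, Status.PERSISTENT, Status.EXCLUDED][
                int(rng.integers(0, 3))
            ]
            reason = (ExclusionReason.ONE_TIME_TRIGGER
                      if status is Status.EXCLUDED else ExclusionReason.NONE)
            outs.append(outcome(i, atype, status, first, last, reason))
        df = time_to_absence_curves(outs, max_day=8)
        got = list(df.itertuples(index=False, name=None))
        assert got == brute_force_curves(outs, 8)

    def test_absent_proportion_nondecreasing(self):
        rng = np.random.default_rng(3)
        outs = [
            outcome(i, status=Status.ABSENT, first=1, last=int(rng.integers(1, 8)))
            for i in range(50)
        ]
        df = time_to_absence_curves(outs)
        for _, g in df.groupby("alert_type"):
            assert g.sort_values("day")["prop_absent_by_day"].is_monotonic_increasing or \
                g.sort_values("day")["prop_absent_by_day"].diff().dropna().ge(0).all()
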