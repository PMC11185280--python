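from __future__ import annotations

import pytest

from alertraster.classify import (
    ClassificationPolicy,
    ContinuityRule,
    ExclusionReason,
    Status,
    apply_exclusions,
    classify_alert,
    classify_dataset,
    compute_ddoa,
)
from alertraster.intervals import build_grid
from alertraster.linkage import build_chains
from alertraster.model import AlertType, Dataset, PatientCase, ScheduleKind
from alertraster.pipeline import analyze_dataset
from alertraster.synth import SynthConfig, generate

from conftest import inject_day_pauses, make_alert, make_rx, ts


class TestComputeDdoa:
    @pytest.mark.parametrize("first,last,expected", [(1, 4, 4), (3, 3, 1), (2, 5, 4)])
    def test_inclusive_interval_count(self, first, last, expected):
        assert compute_ddoa(first, last) == expected

    def test_inverted_indices_rejected(self):
        with pytest.raises(ValueError):
            compute_ddoa(4, 2)


def single_case_dataset(prescriptions, alerts):
    case = PatientCase("C1", ts("2024-03-01T10:00"), ts("2024-03-05T12:00"))
    ds = Dataset([case], prescriptions, alerts)
    ds.validate()
    chains = build_chains(prescriptions)
    grid = build_grid(case, alerts, chains)
    return ds, chains, grid


class TestExclusions:
    def test_one_time_trigger_excluded_first(self):
        rx = make_rx("R1", "C1", "D1", "2024-03-05T09:00", "2024-03-05T09:00",
                     kind=ScheduleKind.ONE_TIME)
        # also first displayed on the discharge day: one_time wins the ordering
        alert = make_alert("A1", "C1", ["R1"], [("2024-03-05T09:00", "2024-03-05T11:00")])
        ds, chains, grid = single_case_dataset([rx], [alert])
        analyzed, excluded = apply_exclusions(ds, {"C1": grid})
        assert analyzed == []
        assert excluded[0].exclusion_reason is ExclusionReason.ONE_TIME_TRIGGER

    def test_interactive_precedes_discharge_day(self):
        rx = make_rx("R1", "C1", "D1", "2024-03-05T08:00", "2024-03-05T12:00")
        alert = make_alert("A1", "C1", ["R1"], [("2024-03-05T08:10", "2024-03-05T11:00")],
                           interactive=True)
        ds, chains, grid = single_case_dataset([rx], [alert])
        _, excluded = apply_exclusions(ds, {"C1": grid})
        assert excluded[0].exclusion_reason is ExclusionReason.INTERACTIVE

    def test_discharge_day_first_display_excluded(self):
        rx = make_rx("R1", "C1", "D1", "2024-03-05T08:00", "2024-03-05T12:00")
        alert = make_alert("A1", "C1", ["R1"], [("2024-03-05T08:10", "2024-03-05T11:00")])
        ds, chains, grid = single_case_dataset([rx], [alert])
        _, excluded = apply_exclusions(ds, {"C1": grid})
        assert excluded[0].exclusion_reason is ExclusionReason.DISCHARGE_DAY_FIRST_DISPLAY
        assert excluded[0].ddoa_days == 1

    def test_ordinary_alert_is_analyzed(self):
        rx = make_rx("R1", "C1", "D1", "2024-03-01T11:00", "2024-03-05T12:00")
        alert = make_alert("A1", "C1", ["R1"], [("2024-03-01T11:10", "2024-03-03T09:00")])
        ds, chains, grid = single_case_dataset([rx], [alert])
        analyzed, excluded = apply_exclusions(ds, {"C1": grid})
        assert [a.alert_id for a in analyzed] == ["A1"]
        assert excluded == []


class TestClassifyAlert:
    def test_displayed_until_discharge_is_persistent(self):
        rx = make_rx("R1", "C1", "D1", "2024-03-02T08:00", "2024-03-05T12:00")
        alert = make_alert("A1", "C1", ["R1"], [("2024-03-02T08:10", "2024-03-05T11:00")])
        _, chains, grid = single_case_dataset([rx], [alert])
        out = classify_alert(grid, chains, alert)
        assert out.status is Status.PERSISTENT
        assert (out.first_index, out.last_index, out.ddoa_days) == (2, 5, 4)
        assert out.absence_index is None

    def test_disappearance_during_continuous_prescription_is_absent(self):
        rx = make_rx("R1", "C1", "D1", "2024-03-01T11:00", "2024-03-04T18:00")
        alert = make_alert("A1", "C1", ["R1"], [("2024-03-01T11:10", "2024-03-02T20:00")])
        _, chains, grid = single_case_dataset([rx], [alert])
        out = classify_alert(grid, chains, alert)
        assert out.status is Status.ABSENT
        assert out.absence_index == 3
        assert out.ddoa_days == 2

    def test_disappearance_with_prescription_end_is_persistent(self):
        # chain ends within interval 2; alert display also ends there
        rx = make_rx("R1", "C1", "D1", "2024-03-01T11:00", "2024-03-02T20:00")
        alert = make_alert("A1", "C1", ["R1"], [("2024-03-01T11:10", "2024-03-02T19:00")])
        _, chains, grid = single_case_dataset([rx], [alert])
        out = classify_alert(grid, chains, alert)
        assert out.status is Status.PERSISTENT
        assert out.ddoa_days == 2

    def test_two_triggers_any_vs_all_policy(self):
        # one chain continues into interval 3, the other ends in interval 2
        rxs = [
            make_rx("R1", "C1", "D1", "2024-03-01T11:00", "2024-03-04T18:00"),
            make_rx("R2", "C1", "D2", "2024-03-01T11:00", "2024-03-02T20:00"),
        ]
        alert = make_alert("A1", "C1", ["R1", "R2"],
                           [("2024-03-01T11:10", "2024-03-02T19:00")])
        _, chains, grid = single_case_dataset(rxs, [alert])
        any_out = classify_alert(grid, chains, alert,
                                 ClassificationPolicy(ContinuityRule.ANY_CHAIN_ACTIVE))
        all_out = classify_alert(grid, chains, alert,
                                 ClassificationPolicy(ContinuityRule.ALL_CHAINS_ACTIVE))
        stay_out = classify_alert(grid, chains, alert,
                                  ClassificationPolicy(ContinuityRule.STAY_ONLY))
        assert any_out.status is Status.ABSENT
        assert all_out.status is Status.PERSISTENT
        assert stay_out.status is Status.ABSENT

    def test_reappearance_after_gap_classified_at_first_disappearance(self, caplog):
        rx = make_rx("R1", "C1", "D1", "2024-03-01T11:00", "2024-03-05T12:00")
        alert = make_alert("A1", "C1", ["R1"], [
            ("2024-03-01T11:10", "2024-03-02T20:00"),
            ("2024-03-04T08:00", "2024-03-04T20:00"),
        ])
        _, chains, grid = single_case_dataset([rx], [alert])
        with caplog.at_level("WARNING"):
            out = classify_alert(grid, chains, alert)
        assert out.status is Status.ABSENT
        assert (out.first_index, out.last_index, out.absence_index) == (1, 2, 3)
        assert "reappears" in caplog.text


class TestDatasetLevelProperties:
    def test_accounting_identity_on_synthetic_data(self):
        ds, _ = generate(SynthConfig(n_cases=80, seed=21, interactive_fraction=0.05))
        res = analyze_dataset(ds)
        counts = res.counts()
        assert counts["excluded"] + counts["absent"] + counts["persistent"] == len(ds.alerts)

    def test_ddoa_bounded_by_stay_length(self):
        ds, _ = generate(SynthConfig(n_cases=80, seed=22))
        res = analyze_dataset(ds)
        n_by_case = {cid: len(g.intervals) for cid, g in res.grids.items()}
        for o in res.outcomes:
            assert 1 <= o.ddoa_days <= n_by_case[o.case_id]
            if o.status is Status.ABSENT:
                assert o.absence_index == o.last_index + 1
                assert o.absence_index <= n_by_case[o.case_id]

    @pytest.mark.parametrize("seed", [3, 17])
    def test_policy_monotonicity_of_absence_sets(self, seed):
        ds, _ = generate(SynthConfig(n_cases=60, seed=seed))
        chains = build_chains(ds.prescriptions)
        absent_sets = {}
        for rule in ContinuityRule:
            res = analyze_dataset(ds, ClassificationPolicy(continuity_rule=rule))
            absent_sets[rule] = {
                o.alert_id for o in res.outcomes if o.status is Status.ABSENT
            }
        assert absent_sets[ContinuityRule.ALL_CHAINS_ACTIVE] <= absent_sets[
            ContinuityRule.ANY_CHAIN_ACTIVE
        ]
        assert absent_sets[ContinuityRule.ANY_CHAIN_ACTIVE] <= absent_sets[
            ContinuityRule.STAY_ONLY
        ]

    def test_pause_injection_changes_no_outcome(self):
        import numpy as np

        ds, _ = generate(SynthConfig(n_cases=60, seed=9, pause_rate=0.0))
        base = classify_dataset(ds, _grids(ds), build_chains(ds.prescriptions))
        fragged = inject_day_pauses(ds, np.random.default_rng(4))
        after = classify_dataset(fragged, _grids(fragged), build_chains(fragged.prescriptions))
        assert base == after


def _grids(ds):
    chains = build_chains(ds.prescriptions)
    by_case = {}
    for c in chains:
        by_case.setdefault(c.case_id, []).append(c)
    alerts = {}
    for a in ds.alerts:
        alerts.setdefault(a.case_id, []).append(a)
    return {
        c.case_id: build_grid(c, alerts.get(c.case_id, []), by_case.get(c.case_id, []))
        for c in ds.cases
    }
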