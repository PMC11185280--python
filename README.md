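# alertraster

Automated event analysis of **passive, noninterruptive medication alerts**
issued by a CPOE/CDSS (computerized physician order entry system with
clinical decision support).

In many European hospital systems, medication alerts are shown in a
separate on-request window and never have to be acknowledged, accepted, or
overridden — so no in-dialog acceptance data exist. The only trace an
accepted alert leaves is an *event* in the medication record: the alert
stops being displayed while its underlying prescription continues.
`alertraster` estimates alert acceptance from exactly that trace, at scale,
for whole inpatient stays.

## Method

Each stay is rasterized into midnight-anchored, half-open **24-hour
intervals** `[start, end)` — the first runs from admission to the next
midnight, the last from the final midnight to discharge. Per interval the
engine records the set of displayed alert IDs and the set of active
*continuous prescriptions*; the coarse interval deliberately absorbs
administrative display interruptions (e.g., ward transfers) so they cannot
masquerade as acceptance.

Prescriptions whose regimen changes appear as separate log entries are
chained back together: a **follow-up prescription** has the same drug and
administration route and starts within 10 minutes (inclusive) of its
predecessor's end. Chains define the denominator of "the prescription
continues".

Three alert groups cannot be evaluated and are excluded, in fixed order:

1. alerts triggered by **one-time prescriptions** (no next-day comparison),
2. alerts **requiring user interaction** to resolve their conditions,
3. alerts **first displayed on the discharge day** (no subsequent interval).

Every remaining alert is classified by comparing consecutive intervals:

- **absent** — the alert ID vanishes from an interval while at least one
  triggering prescription chain is still active there (the acceptance
  proxy);
- **persistent** — the alert is displayed in every consecutive interval
  until discharge, or its disappearance coincides with the end of all
  triggering prescriptions.

The **display duration of alerts (DDoA)** is the inclusive interval count
between first and last display, `last − first + 1` days. Results are
summarized per alert type (DDI, DAI, DP, PIM, PE-MDD) with absence rates
and DDoA median/IQR/range, compared pairwise with 2×2 Pearson χ² tests
(no continuity correction, two-tailed, unadjusted), and reported as
discrete time-to-absence/persistence curves.

Because hospital event logs are not public, the package ships a
**synthetic generator** (`alertraster.synth`) that emulates the structure
the method consumes — stays with median length 7 days, ~16.3% one-time
triggered alerts, ~1.9% discharge-day onsets, split follow-up
prescriptions, intra-day pauses — with per-alert ground-truth labels the
engine must recover exactly.

## Worked example

`python examples/worked_example_stay.py` builds a 5-day stay with four
alerts and prints:

```
alert  days_displayed  ddoa  label
A1     1-4            4     absent
A2     2-5            4     persistent
A3     3              1     absent
A4     5              1     excluded (discharge_day_first_display)
```

A1 is displayed from admission through day 4 and vanishes on day 5 while
its prescription continues — an absent alert with a display duration of 4
days, the method's signal that the alert was likely acted on. A2 runs to
discharge (persistent, DDoA 4); A3 is shown only on day 3 (DDoA 1); A4
first appears on the discharge day, so no subsequent interval exists to
compare against and it is excluded.

`python examples/simulate_and_analyze.py` simulates a 300-case cohort,
prints the per-type summary table, and reports 100.0% recovery of the
generator's truth labels; `examples/compare_policies.py` contrasts the
three continuity rules for multi-trigger alerts.

## Command line

```bash
alertraster simulate --seed 7 --n-cases 300 --out sim/
alertraster analyze --cases sim/cases.csv --rx sim/prescriptions.csv \
    --alerts sim/alerts.csv --out results/ \
    [--continuity-rule any|all|stay] [--interval-hours 24] [--linkage-minutes 10]
alertraster report --outcomes results/outcomes.csv --out report/
```

`analyze` writes `outcomes.csv`, `summary.csv`, `pairwise_tests.csv`,
`curves.csv`, and a JSON run report with stage counts
(total = excluded + absent + persistent).

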