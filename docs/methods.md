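# Methods

## Problem and model

`alertraster` estimates the acceptance of passive, noninterruptive
medication alerts by *event analysis*: instead of in-dialog accept/override
clicks (which such systems do not record), it watches the alert display
itself. The unit of observation is an alert ID over an inpatient stay. The
stay is tiled with half-open, midnight-anchored intervals
`[start, end)` of 24 hours (first interval: admission → midnight; last:
midnight → discharge). Presence of an alert or a prescription chain in an
interval requires strictly positive temporal overlap. Two consecutive
intervals are then compared:

- an alert present in interval *k* but not *k+1*, while at least one of its
  triggering prescription chains is still active in *k+1*, is **absent**
  (detected at `absence_index = k+1`);
- an alert displayed through the stay's final interval, or one whose
  disappearance coincides with the end of every triggering chain, is
  **persistent**.

The display duration of alerts (DDoA) is `last_index − first_index + 1`
intervals, an integer number of days in `[1, stay length]`.

### Assumptions

- Alerts are regularly reviewed, and an alert disappears because its risk
  constellation no longer exists. Absence is therefore a *proxy* for
  acceptance; it cannot distinguish an alert-driven change from a scheduled
  therapy end or a switch for clinical reasons. The absolute absence rate
  overestimates true acceptance to an unknown degree.
- The 24-hour lookback absorbs administrative display interruptions (ward
  transfers trigger automatic prescription pauses and alert redisplay).
  Within-interval timing is deliberately discarded.
- Timestamps are local wall-clock at minute precision; daylight-saving
  shifts are ignored because bucketing keys on the calendar date.

### Numerical / procedural choices

- **Half-open convention everywhere.** A segment or chain ending exactly at
  a midnight belongs to the earlier interval only; zero-duration overlap is
  never presence. This makes rasterization invariant under arbitrary
  refragmentation of display segments.
- **Follow-up linkage window: 10 minutes, boundary inclusive** (a gap of
  exactly 10 minutes links). Inclusive reads "within" conservatively toward
  continuity, which is the rule's purpose — ignoring administrative pauses.
  Configurable (`--linkage-minutes`).
- **Competing follow-up candidates.** If several prescriptions of the same
  drug/route start within the window of one ending prescription, the
  earliest-starting one continues the chain; later candidates start new
  chains (deterministic, order-independent). Overlapping same-drug/route
  prescriptions are duplicate therapy, not follow-ups, and are never
  chained.
- **Exclusion precedence**: one-time trigger → interactive → discharge-day
  first display; the first matching rule is recorded.
- **Terminal absence.** If an alert ID reappears after a full display-free
  interval (the system can redisplay alerts), classification is made at the
  first disappearance — `last_index` is the end of the first contiguous
  display run — and the reappearance is logged as an anomaly rather than
  becoming a second outcome.
- **Continuity rule for multi-trigger alerts** (`ClassificationPolicy`):
  default `any_chain_active` — one surviving chain suffices for absence.
  Requiring all chains would reclassify most resolved interaction alerts
  (where exactly one of the two drugs is changed) as persistent, which
  contradicts the high absence rates such alerts show.  `all_chains_active`
  and `stay_only` are provided for sensitivity analyses; the absent sets
  are provably nested `all ⊆ any ⊆ stay_only`.
- **Interval width** is configurable (`interval_hours`, default 24,
  midnight-of-admission-day anchored); only the 24 h default is exercised
  by the shipped checks.
- **Quartiles** of DDoA use linear interpolation between order statistics
  (numpy default). Commercial statistics packages use other estimators;
  exact IQR values may differ by up to one day on small strata.
- **χ² tests** are 2×2 Pearson tests without Yates continuity correction,
  two-tailed, df = 1, unadjusted across the 10 type pairs. A zero margin is
  reported as degenerate with p = 1. The implementation
  (scipy `chi2_contingency`) is cross-checked in the test suite against the
  closed form `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))` to 1e-9.
- **Time-to-event curves** are simple per-day proportions (absent within
  *t* intervals of first display; persistent with DDoA ≥ *t*), not a
  censoring-adjusted product-limit estimator. They are descriptive, not
  survival estimates.

## Synthetic-data generator

`alertraster.synth` emulates the event-log structure the method consumes,
with per-alert ground truth:

| parameter | default | meaning |
|---|---|---|
| `los_median_days` | 7 | median length of stay; LOS ~ 1 + NegBin(r = 1.2, p solved for the median), giving quartiles 4/13 days |
| `alert_rate` | DP 5.6, DDI 1.73, DAI 0.38, PIM 0.37, PE-MDD 0.30 | expected alerts per case per type (~8.4 total, duplicate prescriptions dominating) |
| `p_absent` | DP .481, DDI .809, DAI .805, PIM .399, PE-MDD .519 | probability an analyzed alert resolves before its prescription ends |
| `one_time_fraction` | 0.163 | share of alerts triggered by one-time prescriptions |
| `discharge_onset_fraction` | 0.019 | share first displayed on the discharge day |
| `interactive_fraction` | 0.0 | share requiring user interaction (0 by default: the excluded-alert accounting the defaults emulate leaves no separate interactive share; tests raise it to exercise the rule) |
| `resolution_day_param` | 0.45 | geometric parameter for extra display days before resolution |
| `pause_rate` | 0.3 | expected intra-day display pauses per alert-day (ward transfers; never span a midnight) |

Truth labels are realized at interval granularity: an absent alert's
display stops at least one full interval before its trigger chains end, a
prescription-end persistent alert's chains all end within its last display
interval, and analyzed alerts are placed only on stays of ≥ 2 intervals.
This makes the labels unambiguous under 24-hour rasterization — the label
recovery the tests assert (100% agreement, any seed) certifies the engine
against the generator's *constructed* ground truth, not against clinical
reality. What passing does **not** show: robustness to sub-interval
ambiguity (segments ending within the same interval as their chain),
irregular documentation, drug-code granularity mismatches, or any clinical
validity of absence-as-acceptance. Follow-up chains are realized as
prescriptions split with 5-minute gaps; each conceptual chain uses a unique
drug code so chaining is exact by construction.

Degenerate inputs: a configuration whose stays are all single-day cannot
host analyzed alerts and raises a config error; `n_cases = 0` yields valid
header-only files; an all-zero `p_absent` yields only persistent analyzed
alerts.

## Problem sizes in the shipped checks

Unit and property tests run cohorts of 10–150 cases; the cohort-arithmetic
checks rebuild the published marginal counts (13,979 alerts; per-type
2×2 tables) as outcome stubs. The acceptance script analyzes the 5-day
worked-example stay plus a 300-case synthetic cohort. These sizes were
chosen to make every check a few seconds at most; the engine itself is
linear in alerts × intervals and handles thousands of cases unchanged.

## Known limitations

- Prescribing-level only: whether drugs were administered is not observed,
  which inflates duplicate-prescription persistence (as-needed orders often
  represent options, not co-administration).
- No inference about *why* an alert disappeared; no control group.
- Drug codes are compared by string equality; therapeutic switches to a
  different substance are by design not follow-ups.
- Input CSV schemas are a canonicalization, not a vendor export format.
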