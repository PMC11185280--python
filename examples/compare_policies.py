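"""Compare continuity rules for judging alert disappearance.

For alerts with several triggering prescriptions (e.g., a drug-drug
interaction involves two drugs), "the prescription continues" is ambiguous.
Three rules are supported: at least one triggering chain still active
(default), all chains still active, or ignore prescriptions entirely and
count any pre-discharge disappearance as absent. The absent sets are nested:
all-chains ⊆ any-chain ⊆ stay-only.
"""

from alertraster import (
    ClassificationPolicy, ContinuityRule, Status, SynthConfig,
    analyze_dataset, generate,
)

ds, _ = generate(SynthConfig(n_cases=200, seed=3))

print(f"{len(ds.alerts)} alerts across {len(ds.cases)} cases\n")
print("continuity rule      absent  persistent  excluded")
for rule in ContinuityRule:
    res = analyze_dataset(ds, ClassificationPolicy(continuity_rule=rule))
    c = res.counts()
    print(f"{rule.value:<20} {c['absent']:<7} {c['persistent']:<11} {c['excluded']}")

# The stay-only rule overcounts absence: disappearances caused by a
# prescription simply ending are misread as acceptance. The all-chains rule
# undercounts it: resolving one of two interacting drugs no longer counts.
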