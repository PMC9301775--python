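"""Generate a small synthetic cohort and apply the quality-control rules.

Each participant gets 74 harm-aversion trials (70 money-vs-shocks trade-offs
plus 4 attention checks) and 48 work-vs-rest effort trials, with choices
simulated from their true model parameters.
"""

from prosocial import RunConfig, apply_exclusions, simulate_cohort

config = RunConfig(seed=42, n=40, miss_rate=0.02, check_fail_prob=0.02)
cohort = simulate_cohort(config)

first = cohort.harm_records[0]
print("participant 0, first three harm trials:")
for rec in first[:3]:
    t = rec.trial
    print(
        f"  beneficiary={t.beneficiary:5s}  dMoney={t.d_money:5.1f}  "
        f"dShocks={t.d_shocks:4.0f}  choice={rec.choice}"
    )

retained, reports = apply_exclusions(cohort.harm_records, cohort.effort_records)
n_att = sum(r.reason in ("attention_check", "both") for r in reports)
n_miss = sum(r.reason in ("missed_trials", "both") for r in reports)
print(f"\nQC: {len(retained)}/{config.n} retained "
      f"({n_att} failed an attention check, {n_miss} missed >10% of effort trials)")
print("Excluded participants never reach the model-fitting or trait analyses.")
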