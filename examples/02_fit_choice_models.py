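"""Fit both choice models to one simulated participant.

The harm-aversion model weighs money against shocks through κ per
beneficiary (ΔV = (1−κ)Δm − κΔs); the effort model discounts reward
parabolically (SV = R − λE²). Hyperaltruism is κ_other − κ_self and
prosocial effort is −(λ_other − λ_self): positive values mean the
participant is costlier to themselves to spare or benefit the other person.
"""

from prosocial import (
    EffortParams,
    HarmParams,
    generate_effort_trialset,
    generate_harm_trialset,
    hyperaltruism,
    prosocial_effort,
    simulate_effort_choices,
    simulate_harm_choices,
)
from prosocial.effort import fit as fit_effort
from prosocial.harm import fit as fit_harm

true_harm = HarmParams(kappa_self=0.37, kappa_other=0.45, beta_self=5.0, beta_other=5.0)
true_effort = EffortParams(lambda_self=0.02, lambda_other=0.11, beta=2.0)

harm_trials = generate_harm_trialset(seed=0)
effort_trials = generate_effort_trialset()
harm_rec = simulate_harm_choices(true_harm, harm_trials, seed=1)
effort_rec = simulate_effort_choices(true_effort, effort_trials, seed=2, miss_rate=0.02)

hfit = fit_harm(harm_rec, seed=3)
efit = fit_effort(effort_rec, seed=4)

print("harm aversion (35 trials/condition):")
print(f"  true  kappa_self={true_harm.kappa_self:.3f}  kappa_other={true_harm.kappa_other:.3f}")
print(f"  fit   kappa_self={hfit.params.kappa_self:.3f}  kappa_other={hfit.params.kappa_other:.3f}"
      f"  (NLL={hfit.nll:.2f})")
print("effort discounting (48 trials):")
print(f"  true  lambda_self={true_effort.lambda_self:.3f}  lambda_other={true_effort.lambda_other:.3f}")
print(f"  fit   lambda_self={efit.params.lambda_self:.3f}  lambda_other={efit.params.lambda_other:.3f}"
      f"  (NLL={efit.nll:.2f}, {efit.n_missed_excluded} missed trials dropped)")
print(f"\nindices: hyperaltruism={hyperaltruism(hfit.params):+.3f}  "
      f"prosocial effort={prosocial_effort(efit.params):+.3f}")
print("(positive hyperaltruism: more averse to harming the other than oneself;")
print(" negative prosocial effort: discounts the other's rewards more steeply)")
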