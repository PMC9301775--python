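"""Parameter-recovery check at the tasks' actual trial counts.

Known parameters are drawn, choices simulated (35 harm trials per condition,
48 effort trials), and the models refitted. Good rank recovery of the
"other"-condition parameters is what licenses interpreting the fitted
indices as individual-difference measures.
"""

from scipy.stats import spearmanr

from prosocial import run_recovery

df = run_recovery(n=50, seed=0)

for par in ("kappa_other", "lambda_other"):
    rho = spearmanr(df[f"{par}_true"], df[f"{par}_hat"]).statistic
    bias = (df[f"{par}_hat"] - df[f"{par}_true"]).mean()
    print(f"{par}: Spearman(true, recovered) = {rho:.3f}, mean bias = {bias:+.4f}")
print("\nrho > 0.8 indicates the trial sets identify the parameters well;")
print("bias near zero shows the bounded MLE does not systematically shrink them.")
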