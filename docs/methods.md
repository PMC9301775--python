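# Methods

## Choice models

Both tasks are modelled as binary softmax choice. The harm-aversion model
values the harmful-minus-helpful difference as ΔV = (1−κ)Δm − κΔs, with
κ ∈ [0, 1] per beneficiary condition; κ = Δm/(Δm+Δs) is the indifference
point of a trial, so κ is identifiable only where the trial set's
indifference ratios bracket it. P(harmful) = logistic(βΔV) with
β ∈ [0, 100]; at β = 0 choice is random, near 100 effectively
deterministic. The effort model values a work offer as SV = R − λE² with
λ ∈ [0, 0.5] per condition and one shared β ∈ (0.01, 30];
P(work) = e^{βSV}/(e^{β·1} + e^{βSV}) against the fixed 1-credit rest.
The λ cap reflects task geometry: with effort units E ∈ {3,5,7,9} and
rewards 2–4 credits, every offer is worth less than resting once
λ ≥ 3/E_min² ≈ 0.33, so larger values change no predicted choice. The
effort levels 30/50/70/90 % are coded numerically as tenths of the
calibrated maximum ({3,5,7,9}); this is the only coding consistent with the
cap rationale and with λ values in the observed 0.02–0.11 range, and any
monotone recoding would leave the rank-based downstream statistics
unchanged.

### Fitting

Parameters are estimated per participant by bounded maximum likelihood
(L-BFGS-B, tight tolerances, β optimized on a log scale), with a fixed
moderate start plus `n_starts − 1` (default 9) uniform random restarts; ties
are broken by lowest NLL, then lowest κ_other / λ_other. The harm model's
two conditions have separable likelihoods and are fitted independently; the
effort model is fitted jointly because β is shared. Choice probabilities
are floored at 1e−12 inside the log-likelihood. Boundary estimates are
retained (and flagged), not censored: an always-helpful chooser genuinely
has κ above the set's largest indifference ratio, where the likelihood is
flat — estimates there are reported as bound values, identified only up to
that flat region. Missed effort trials are dropped from the likelihood
(misses are not modelled); attention checks never enter any likelihood.
Test oracles: dense grid search (κ step 0.01 × β ∈ {0.5,…,20}; λ step 0.005
× β ∈ {0.5,…,10}) must never beat the optimizer by more than 1e−3 nats.

## Quality control

A participant is excluded if they pick the dominated option on ≥ 1 of the 4
harm-task attention checks, or miss strictly more than 10 % of the 48
effort trials ("more than 10 %" read as a strict inequality: 4/48 retained,
5/48 excluded; the denominator is taken as all 48 trials). Exclusion
removes the participant from every downstream stage.

## Univariate statistics

Wilcoxon signed-rank tests use the normal approximation with tie-corrected
variance and no continuity correction, dropping zero differences — the
common statistical-package default; the z statistic matches one built from
the exact enumerated null moments whenever there are no ties. Spearman
correlations use average ranks. The comparison of two correlations uses the
independent-samples Fisher-Z test on absolute values — a fidelity choice
mirroring common practice for this analysis, not an endorsement: the two
correlations share a sample, so the test is approximate. The two
repeated-measures ANOVAs (work proportion over beneficiary × effort and
beneficiary × reward) apply the Greenhouse–Geisser correction whenever an
effect has ≥ 3 levels (ε estimated from the per-subject covariance of cell
means, via pingouin), reporting fractional corrected dfs and partial η².
A constant dependent variable yields F = 0, p = 1 rather than NaN.

## CCA, permutation inference, commonality

Columns of both sets are z-scored (n−1 denominator) after listwise
deletion. The solution is the SVD of R_xx^{−1/2} R_xy R_yy^{−1/2} with
symmetric (eigendecomposition) whitening; rank deficiency raises an error
naming the implicated columns. Standardized weights are back-transformed
singular vectors, giving unit-variance, mutually uncorrelated variates;
loadings are correlations of observed variables with their own variate, and
cross-loadings satisfy cross = loading × r exactly. Each function's sign is
anchored so the first Y variable (hyperaltruism) loads positively, matching
the convention that the prosocial variate points toward prosociality.
Sequential significance uses Wilks' Λ_k = Π_{i≥k}(1−r_i²) with Rao's F
approximation (for p = 18, q = 2, n = 325 this yields F(36, 610) and
F(17, 306)). The permutation test shuffles Y rows jointly — preserving
within-set structure; shuffling X instead would be equivalent — with Roy's
largest root (largest squared canonical correlation) as statistic and
p = (1 + #{null ≥ obs})/(1 + n_perm), default 1,000 permutations.

Interpretation is restricted to function 1; variables are classified by the
0.3 threshold on |loading| and |weight| (contributor / collinear
contributor / suppressor candidate / negligible). Commonality analysis runs
on the traits with |loading| ≥ 0.3 or |weight| ≥ 0.3, against the
prosocial-set variate scores of function 1 as criterion (the natural
criterion for "explaining the predicted dimension"; other criterion choices
exist and would change the numbers, not the partition identity):
total_j = squared zero-order correlation, unique_j = R²(all) − R²(all∖j),
common_j = total_j − unique_j, so unique + common = total to machine
precision and negative common flags suppression. The all-subsets partition
is refused above 20 predictors.

## Synthetic cohorts

The generator emulates the study conditions: 35 regular harm trials plus 2
attention checks per beneficiary condition (the original optimized trial
sets are not public, so identifiability is engineered instead — target
indifference ratios are stratified over (0,1), covering ≥ 8 of 10 deciles,
with Δm on a 0.1 grid in [0.1, 10] and integer Δs in [1, 19]); the fixed
48-trial effort design (2 × 4 × 3 cells, 2 repeats); Bernoulli choices from
the models; compliant check behavior with a plantable fail probability
(default 0.02/check, ≈ 8 % exclusion over 4 checks, matching observed
exclusion frequencies); and uniform missingness on effort trials only
(default rate 0.02), since only that task was time-limited.

The 18-trait battery carries a single standard-normal latent factor A with
default loadings IRI-EC +0.60, IRI-PT +0.45, AMI-ES −0.55, TAS-EOT −0.45,
SRP-Aff −0.45, SRP-I −0.40 and zero elsewhere — a "broad affective
cluster": empathic concern and perspective taking up, emotional apathy,
externally oriented thinking and affective/interpersonal psychopathy down.
Trait scores are continuous, x_j = l_j A + √(1−l_j²)ε_j, affinely placed on
plausible instrument scales (cosmetic for all rank/correlation-based
stages; no discretization to questionnaire ranges). Both prosociality
indices load equally on A with noise calibrated analytically so the
population first canonical correlation hits a target (default 0.4): with
s = Σ l_j²/(1−l_j²), R_X = √(s/(1+s)) caps what the trait set can transmit,
and the index loading c solves r₁ = R_X·√(2c²/(1+c²)); targets above 0.95
or beyond R_X raise an error, and zero loadings give an exactly null
cohort. Index means are +0.08 (hyperaltruism) and −0.08 (prosocial effort,
i.e. a +0.08 prosocial-apathy contrast) with sds 0.20 and 0.12 —
magnitudes in line with the behavioral effect sizes the models are meant to
produce. Ground-truth parameters are built from the indices
(κ_self ~ N(0.37, 0.22) clipped to [0,1], κ_other = κ_self + hyperaltruism
clipped; λ_self ~ N(0.02, 0.04) clipped to [0, 0.5], λ_other analogous;
β's lognormal around 5 (harm) and 2 (effort)) and stored beside every
cohort for recovery harnesses only — fitting stages never see them.

What the generator does **not** emulate: real questionnaire discreteness
and skew, multi-factor trait structure, non-uniform or strategic
missingness, within-session learning or fatigue, execution failure on
chosen work, and bot-like responding. Passing tests therefore show the
pipeline is correct and well calibrated under the planted model, not that
the scientific conclusions would replicate on real cohorts.

## Problem sizes and determinism

Default experiment sizes were chosen to keep each validation suite at
desk scale while leaving sampling error well below the tested margins:
parameter recovery uses 200 simulated participants; permutation-test
calibration uses 500 null cohorts × 200 permutations (rejection rate
checked at 0.05 ± 0.02) and power 50 planted cohorts; planted-effect
detection uses 100 replicate cohorts at n = 325. Every stochastic stage
consumes an explicit seed; a pipeline run is bit-for-bit reproducible from
its `RunConfig`, and CSV round-trips reproduce cohorts exactly.

## Known limitations

- Sample canonical correlations are upward-biased at p = 18, n = 325
  (≈ +0.06 at a population value of 0.4); the generator targets the
  population value and makes no small-sample correction.
- κ is not scale-free under currency rescaling (Δm in different units
  shifts the indifference ratios); only trial-order invariance is
  guaranteed.
- When β hits a bound the likelihood is locally flat in κ/λ, so point
  estimates there are identified only up to the flat region (the NLL, and
  all rank statistics in practice, are unaffected).
- The Fisher-Z comparison treats overlapping correlations as independent
  (see above).
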