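"""Parabolic effort-discounting model: SV = R − λE² against a 1-credit rest.

λ ∈ [0, 0.5] is the effort discount rate per beneficiary condition (at the
0.5 cap every offer is worth less than resting, so larger values are not
identifiable); a single temperature β > 0 is shared across conditions.  The
work-vs-rest softmax is P(work) = e^{βSV} / (e^{β·1} + e^{βSV}).  Prosocial
effort is the reverse-coded apathy contrast −(λ_other − λ_self).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .trials import REST_REWARD

LAMBDA_BOUNDS = (0.0, 0.5)
BETA_BOUNDS = (0.01, 30.0)
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class EffortParams:
    lambda_self: float
    lambda_other: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("lambda_self", "lambda_other"):
            v = getattr(self, name)
            if not LAMBDA_BOUNDS[0] <= v <= LAMBDA_BOUNDS[1]:
                raise ValueError(f"{name}={v} outside {LAMBDA_BOUNDS}")
        if not BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]:
            raise ValueError(f"beta={self.beta} outside {BETA_BOUNDS}")

    def lam(self, beneficiary: str) -> float:
        return self.lambda_self if beneficiary == "self" else self.lambda_other


@dataclass(frozen=True)
class EffortFit:
    params: EffortParams
    nll: float
    converged: bool
    n_starts: int
    n_missed_excluded: int


def subjective_value(trial, lam: float) -> float:
    """Discounted value of the work offer, R − λE²."""
    if not LAMBDA_BOUNDS[0] <= lam <= LAMBDA_BOUNDS[1]:
        raise ValueError(f"lambda={lam} outside [0, 0.5]")
    return trial.reward - lam * trial.effort_units**2


def p_work(sv, beta: float):
    """P(work) = e^{βSV}/(e^{β·rest} + e^{βSV}); rest is worth 1 credit."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return expit(beta * (np.asarray(sv, dtype=float) - REST_REWARD))


def _arrays(records, beneficiary: str):
    r, e, y = [], [], []
    for rec in records:
        if rec.missed or rec.trial.beneficiary != beneficiary:
            continue
        r.append(rec.trial.reward)
        e.append(rec.trial.effort_units)
        y.append(1.0 if rec.choice == "work" else 0.0)
    return np.asarray(r), np.asarray(e), np.asarray(y)


def _nll(lam_s, lam_o, beta, data) -> float:
    total = 0.0
    for lam, (r, e, y) in zip((lam_s, lam_o), data):
        p = expit(beta * (r - lam * e**2 - REST_REWARD))
        p_obs = np.where(y == 1.0, p, 1.0 - p)
        total += -np.sum(np.log(np.maximum(p_obs, PROB_FLOOR)))
    return float(total)


def negative_log_likelihood(params: EffortParams, records) -> float:
    """−Σ log P(observed) over non-missed trials; missed trials are dropped."""
    data = [_arrays(records, c) for c in ("self", "other")]
    if all(d[0].size == 0 for d in data):
        raise ValueError("all trials missed or empty record set")
    return _nll(params.lambda_self, params.lambda_other, params.beta, data)


def fit(records, n_starts: int = 10, seed: int | None = None) -> EffortFit:
    """Joint bounded MLE of (λ_self, λ_other, β) with multi-start L-BFGS-B;
    β is optimized on a log scale."""
    rng = np.random.default_rng(seed)
    n_missed = sum(1 for rec in records if rec.missed)
    data = [_arrays(records, c) for c in ("self", "other")]
    for cond, (r, _, _) in zip(("self", "other"), data):
        if r.size == 0:
            raise ValueError(f"no usable (non-missed) trials in condition {cond!r}")

    lo, hi = np.log(BETA_BOUNDS[0]), np.log(BETA_BOUNDS[1])

    def objective(x):
        return _nll(x[0], x[1], np.exp(x[2]), data)

    starts = [(0.05, 0.05, np.log(2.0))]
    starts += [
        (
            rng.uniform(*LAMBDA_BOUNDS),
            rng.uniform(*LAMBDA_BOUNDS),
            rng.uniform(lo, hi),
        )
        for _ in range(n_starts - 1)
    ]
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[LAMBDA_BOUNDS, LAMBDA_BOUNDS, (lo, hi)],
            options={"ftol": 1e-12, "gtol": 1e-9},
        )
        any_ok = any_ok or bool(res.success)
        key = (round(float(res.fun), 9), round(float(res.x[1]), 9))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    params = EffortParams(
        float(res.x[0]), float(res.x[1]), float(np.clip(np.exp(res.x[2]), *BETA_BOUNDS))
    )
    return EffortFit(params, float(res.fun), any_ok, n_starts, n_missed)


def prosocial_effort(params: EffortParams) -> float:
    """Reverse-coded prosocial apathy, −(λ_other − λ_self); higher = more prosocial."""
    return -(params.lambda_other - params.lambda_self)
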