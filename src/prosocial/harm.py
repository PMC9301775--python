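"""Harm-aversion choice model: ΔV = (1−κ)Δm − κΔs with a softmax link.

κ ∈ [0, 1] weighs money against shocks: κ = 0 accepts any profit regardless
of shocks, κ → 1 sacrifices any profit to avoid shocks.  Each beneficiary
condition has its own (κ, β); the softmax temperature β ∈ [0, 100] sets choice
determinism (β = 0 is random choice, β ≈ 100 a step function).  Parameters are
fitted per participant by bounded maximum likelihood with random restarts, and
the hyperaltruism index is κ_other − κ_self.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

KAPPA_BOUNDS = (0.0, 1.0)
BETA_BOUNDS = (0.0, 100.0)
PROB_FLOOR = 1e-12
_LOG_EPS = 1e-3  # β is optimized as log(β + ε) for stability


@dataclass(frozen=True)
class HarmParams:
    kappa_self: float
    kappa_other: float
    beta_self: float
    beta_other: float

    def __post_init__(self) -> None:
        for name in ("kappa_self", "kappa_other"):
            v = getattr(self, name)
            if not KAPPA_BOUNDS[0] <= v <= KAPPA_BOUNDS[1]:
                raise ValueError(f"{name}={v} outside {KAPPA_BOUNDS}")
        for name in ("beta_self", "beta_other"):
            v = getattr(self, name)
            if not BETA_BOUNDS[0] <= v <= BETA_BOUNDS[1]:
                raise ValueError(f"{name}={v} outside {BETA_BOUNDS}")

    def kappa(self, beneficiary: str) -> float:
        return self.kappa_self if beneficiary == "self" else self.kappa_other

    def beta(self, beneficiary: str) -> float:
        return self.beta_self if beneficiary == "self" else self.beta_other


@dataclass(frozen=True)
class HarmFit:
    params: HarmParams
    nll: float
    converged: bool
    n_starts: int
    at_bound: bool = False


def delta_value(trial, kappa: float) -> float:
    """Harmful-minus-helpful value difference (1−κ)Δm − κΔs."""
    if not KAPPA_BOUNDS[0] <= kappa <= KAPPA_BOUNDS[1]:
        raise ValueError(f"kappa={kappa} outside [0, 1]")
    return (1.0 - kappa) * trial.d_money - kappa * trial.d_shocks


def p_harmful(delta_v, beta: float):
    """Softmax probability of the harmful option, 1/(1+e^{−βΔV})."""
    if not BETA_BOUNDS[0] <= beta <= BETA_BOUNDS[1]:
        raise ValueError(f"beta={beta} outside {BETA_BOUNDS}")
    return expit(beta * np.asarray(delta_v, dtype=float))


def _arrays(records, beneficiary: str):
    """(Δm, Δs, chose_harmful) arrays for one condition's regular records."""
    dm, ds, y = [], [], []
    for rec in records:
        t = rec.trial
        if t.is_attention_check:
            raise ValueError("likelihood records must exclude attention checks")
        if t.beneficiary != beneficiary:
            continue
        if t.d_money == 0 and t.d_shocks == 0:
            raise ValueError("degenerate trial with zero money and shock deltas")
        dm.append(t.d_money)
        ds.append(t.d_shocks)
        y.append(1.0 if rec.choice == "harmful" else 0.0)
    return np.asarray(dm), np.asarray(ds), np.asarray(y)


def _condition_nll(kappa: float, beta: float, dm, ds, y) -> float:
    p = expit(beta * ((1.0 - kappa) * dm - kappa * ds))
    p_obs = np.where(y == 1.0, p, 1.0 - p)
    return float(-np.sum(np.log(np.maximum(p_obs, PROB_FLOOR))))


def negative_log_likelihood(params: HarmParams, records) -> float:
    """−Σ log P(observed choice) over regular trials of both conditions."""
    if not records:
        raise ValueError("empty record set")
    total = 0.0
    for cond in ("self", "other"):
        dm, ds, y = _arrays(records, cond)
        if dm.size:
            total += _condition_nll(params.kappa(cond), params.beta(cond), dm, ds, y)
    return total


def _fit_condition(dm, ds, y, n_starts: int, rng) -> tuple[float, float, float, bool]:
    lo, hi = np.log(BETA_BOUNDS[0] + _LOG_EPS), np.log(BETA_BOUNDS[1] + _LOG_EPS)

    def objective(x):
        kappa, u = x
        return _condition_nll(kappa, np.exp(u) - _LOG_EPS, dm, ds, y)

    starts = [(0.5, np.log(5.0 + _LOG_EPS))]
    starts += [
        (rng.uniform(*KAPPA_BOUNDS), rng.uniform(lo, hi)) for _ in range(n_starts - 1)
    ]
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=[KAPPA_BOUNDS, (lo, hi)],
            options={"ftol": 1e-12, "gtol": 1e-9}
        )
        any_ok = any_ok or bool(res.success)
        # ties: lowest NLL, then lowest kappa
        key = (round(float(res.fun), 9), round(float(res.x[0]), 9))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    kappa = float(res.x[0])
    beta = float(np.clip(np.exp(res.x[1]) - _LOG_EPS, *BETA_BOUNDS))
    return kappa, beta, float(res.fun), any_ok


def fit(records, n_starts: int = 10, seed: int | None = None) -> HarmFit:
    """Per-participant MLE; self and other likelihoods are separable, so each
    condition's (κ, β) is optimized independently with multi-start L-BFGS-B."""
    rng = np.random.default_rng(seed)
    records = [r for r in records if not r.trial.is_attention_check]
    out = {}
    nll = 0.0
    converged = True
    for cond in ("self", "other"):
        dm, ds, y = _arrays(records, cond)
        if dm.size == 0:
            raise ValueError(f"no regular trials in condition {cond!r}")
        kappa, beta, cond_nll, ok = _fit_condition(dm, ds, y, n_starts, rng)
        out[cond] = (kappa, beta)
        nll += cond_nll
        converged = converged and ok
    params = HarmParams(out["self"][0], out["other"][0], out["self"][1], out["other"][1])
    at_bound = any(
        k in (KAPPA_BOUNDS[0], KAPPA_BOUNDS[1])
        for k in (params.kappa_self, params.kappa_other)
    )
    return HarmFit(params, nll, converged, n_starts, at_bound)


def hyperaltruism(params: HarmParams) -> float:
    """κ_other − κ_self: excess aversion to harming others over oneself."""
    return params.kappa_other - params.kappa_self
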