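"""Trial-set generators for the two cost–benefit tasks.

The harm-aversion task trades money for hypothetical electric shocks that go
either to the decider ("self") or to an unknown receiver ("other").  Each
regular trial offers a *harmful* option (more money, more shocks) against a
*helpful* one (less money, fewer shocks), summarized by the positive deltas
``d_money`` (Δm) and ``d_shocks`` (Δs).  A participant with harm-aversion
weight κ is indifferent when κ = Δm / (Δm + Δs), so identifiability of κ over
(0, 1) requires the generated indifference ratios to span that interval; the
generator stratifies ratios to guarantee it.

The prosocial-effort task offers a "work" option (reward R ∈ {2,3,4} credits
at effort level 30/50/70/90 % of a calibrated maximum) against a fixed "rest"
option worth 1 credit, half the trials benefiting self and half the other
person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BENEFICIARIES = ("self", "other")

#: numeric effort coding for the 30/50/70/90 % levels (tenths of the maximum)
EFFORT_UNITS = {30: 3.0, 50: 5.0, 70: 7.0, 90: 9.0}
EFFORT_LEVELS = (30, 50, 70, 90)
REWARD_LEVELS = (2, 3, 4)
REST_REWARD = 1.0


@dataclass(frozen=True)
class HarmTrial:
    """One money-vs-shocks decision problem.

    ``d_money`` and ``d_shocks`` are harmful-minus-helpful differences.
    Regular trials have both positive (a genuine trade-off); attention checks
    have one negative so that one option dominates.
    """

    trial_id: int
    beneficiary: str
    d_money: float
    d_shocks: float
    is_attention_check: bool = False

    def __post_init__(self) -> None:
        if self.beneficiary not in BENEFICIARIES:
            raise ValueError(f"beneficiary must be one of {BENEFICIARIES}")
        if not self.is_attention_check:
            if not (self.d_money > 0 and self.d_shocks > 0):
                raise ValueError("regular trials need d_money > 0 and d_shocks > 0")
        else:
            dominated = (self.d_money > 0 and self.d_shocks < 0) or (
                self.d_money < 0 and self.d_shocks > 0
            )
            if not dominated:
                raise ValueError("attention checks need a dominated option")

    @property
    def dominant_choice(self) -> str:
        """Obviously better option on an attention check trial."""
        if not self.is_attention_check:
            raise ValueError("regular trials have no dominant option")
        return "harmful" if self.d_money > 0 else "helpful"


@dataclass(frozen=True)
class EffortTrial:
    """One work-vs-rest offer: R credits for effort E, against 1 credit for rest."""

    trial_id: int
    beneficiary: str
    reward: int
    effort_level: int
    effort_units: float
    rest_reward: float = REST_REWARD

    def __post_init__(self) -> None:
        if self.beneficiary not in BENEFICIARIES:
            raise ValueError(f"beneficiary must be one of {BENEFICIARIES}")
        if self.effort_level not in EFFORT_UNITS:
            raise ValueError(f"effort_level must be one of {EFFORT_LEVELS}")


def generate_harm_trialset(
    n_regular_per_condition: int = 35,
    n_checks_per_condition: int = 2,
    money_range: tuple[float, float] = (0.1, 10.0),
    shock_range: tuple[int, int] = (1, 19),
    seed: int | None = None,
) -> list[HarmTrial]:
    """Generate a harm-aversion trial set with identifiable κ by construction.

    For each condition, target indifference ratios Δm/(Δm+Δs) are stratified
    over (0, 1); a shock delta is drawn and the money delta set (on a 0.1
    grid) to hit the target ratio, subject to ``money_range``.

    Parameters
    ----------
    n_regular_per_condition
        Regular (trade-off) trials per beneficiary condition; the default 35
        gives the task's 70 regular trials.
    n_checks_per_condition
        Attention-check trials per condition (default 2, i.e. 4 overall).
    money_range, shock_range
        Admissible Δm (currency units) and Δs (shock counts).
    """
    if n_regular_per_condition < 1:
        raise ValueError("need at least one regular trial per condition")
    if n_checks_per_condition < 0:
        raise ValueError("n_checks_per_condition must be >= 0")
    m_lo, m_hi = float(money_range[0]), float(money_range[1])
    s_lo, s_hi = int(shock_range[0]), int(shock_range[1])
    if not (0 < m_lo < m_hi):
        raise ValueError("money_range must be positive with nonzero width")
    if not (0 < s_lo < s_hi):
        raise ValueError("shock_range must be positive with nonzero width")

    rng = np.random.default_rng(seed)
    trials: list[HarmTrial] = []
    tid = 0
    for beneficiary in BENEFICIARIES:
        n = n_regular_per_condition
        # stratified indifference ratios, jittered away from stratum edges
        ratios = (np.arange(n) + rng.uniform(0.1, 0.9, size=n)) / n
        rng.shuffle(ratios)
        for r in ratios:
            # cap Δs so the implied Δm stays inside money_range
            s_cap = int(np.floor(m_hi * (1.0 - r) / r))
            ds = int(rng.integers(s_lo, min(s_hi, max(s_lo, s_cap)) + 1))
            dm = float(np.clip(np.round(r / (1.0 - r) * ds, 1), max(m_lo, 0.1), m_hi))
            trials.append(HarmTrial(tid, beneficiary, dm, ds))
            tid += 1
        for k in range(n_checks_per_condition):
            dm = float(np.round(rng.uniform(m_lo + 0.1, m_hi), 1))
            ds = int(rng.integers(s_lo, s_hi + 1))
            if k % 2 == 0:  # harmful option dominates: more money, fewer shocks
                trials.append(HarmTrial(tid, beneficiary, dm, -ds, True))
            else:  # helpful option dominates
                trials.append(HarmTrial(tid, beneficiary, -dm, ds, True))
            tid += 1
    return trials


def generate_effort_trialset() -> list[EffortTrial]:
    """Generate the 48-trial effort task: 2 beneficiaries × 4 efforts × 3 rewards × 2."""
    trials = []
    tid = 0
    for beneficiary in BENEFICIARIES:
        for _repeat in range(2):
            for effort in EFFORT_LEVELS:
                for reward in REWARD_LEVELS:
                    trials.append(
                        EffortTrial(tid, beneficiary, reward, effort, EFFORT_UNITS[effort])
                    )
                    tid += 1
    return trials


def indifference_ratio_coverage(trials: list[HarmTrial], n_bins: int = 10) -> int:
    """Number of equal-width bins of (0,1) hit by the regular trials' Δm/(Δm+Δs)."""
    ratios = [
        t.d_money / (t.d_money + t.d_shocks) for t in trials if not t.is_attention_check
    ]
    hit = np.unique(np.clip((np.asarray(ratios) * n_bins).astype(int), 0, n_bins - 1))
    return int(hit.size)
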