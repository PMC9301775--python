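"""Choice simulation from known model parameters.

Simulated agents choose stochastically according to the softmax choice
probabilities of the harm-aversion and effort-discounting models; compliant
agents always take the dominant option on attention checks (a fail
probability can be planted to create QC violators), and effort-task trials
can be missed uniformly at random (the harm task was not time-limited, so
misses occur only in the effort task).
"""

from __future__ import annotations

from dataclasses import dataclass

from numpy.random import default_rng

from . import effort as effort_model
from . import harm as harm_model
from .trials import EffortTrial, HarmTrial


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed decision; ``choice`` is None iff the trial was missed."""

    trial: HarmTrial | EffortTrial
    choice: str | None
    missed: bool = False

    def __post_init__(self) -> None:
        if self.missed and self.choice is not None:
            raise ValueError("missed trials carry no choice")
        if self.missed and isinstance(self.trial, HarmTrial):
            raise ValueError("harm-task trials cannot be missed")


def simulate_harm_choices(
    params: harm_model.HarmParams,
    trials,
    seed: int | None = None,
    check_fail_prob: float = 0.0,
) -> list[ChoiceRecord]:
    """Bernoulli choices from the harm-aversion model.

    Attention checks get the dominant option with probability
    ``1 − check_fail_prob`` (0 simulates a fully compliant participant).
    """
    rng = default_rng(seed)
    records = []
    for trial in trials:
        if trial.is_attention_check:
            choice = trial.dominant_choice
            if check_fail_prob > 0 and rng.random() < check_fail_prob:
                choice = "helpful" if choice == "harmful" else "harmful"
        else:
            if trial.d_money == 0 and trial.d_shocks == 0:
                raise ValueError("degenerate trial with zero deltas")
            dv = harm_model.delta_value(trial, params.kappa(trial.beneficiary))
            p = harm_model.p_harmful(dv, params.beta(trial.beneficiary))
            choice = "harmful" if rng.random() < p else "helpful"
        records.append(ChoiceRecord(trial, choice))
    return records


def simulate_effort_choices(
    params: effort_model.EffortParams,
    trials,
    seed: int | None = None,
    miss_rate: float = 0.0,
) -> list[ChoiceRecord]:
    """Bernoulli work/rest choices; a fraction ≈ miss_rate is flagged missed."""
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError("miss_rate must be in [0, 1)")
    rng = default_rng(seed)
    records = []
    for trial in trials:
        if miss_rate > 0 and rng.random() < miss_rate:
            records.append(ChoiceRecord(trial, None, missed=True))
            continue
        sv = effort_model.subjective_value(trial, params.lam(trial.beneficiary))
        p = effort_model.p_work(sv, params.beta)
        choice = "work" if rng.random() < p else "rest"
        records.append(ChoiceRecord(trial, choice))
    return records
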