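"""CSV interfaces for cohorts and results tables.

Trial-level data use a single long table (one row per participant × trial,
harm and effort tasks mixed, task-specific columns left empty); traits and
ground truth are wide per-participant tables.  Readers reconstruct the
in-memory objects exactly, so a generated cohort round-trips bit-identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ChoiceRecord
from .traits import TRAIT_NAMES
from .trials import EFFORT_UNITS, EffortTrial, HarmTrial

TRIAL_COLUMNS = (
    "participant_id",
    "task",
    "trial_id",
    "beneficiary",
    "d_money",
    "d_shocks",
    "reward",
    "effort_level",
    "is_attention_check",
    "choice",
    "missed",
)


def trials_frame(harm_by_pid: dict, effort_by_pid: dict) -> pd.DataFrame:
    rows = []
    for pid, records in harm_by_pid.items():
        for rec in records:
            t = rec.trial
            rows.append(
                dict(
                    participant_id=pid, task="harm", trial_id=t.trial_id,
                    beneficiary=t.beneficiary, d_money=t.d_money,
                    d_shocks=t.d_shocks, reward=None, effort_level=None,
                    is_attention_check=t.is_attention_check, choice=rec.choice,
                    missed=rec.missed,
                )
            )
    for pid, records in effort_by_pid.items():
        for rec in records:
            t = rec.trial
            rows.append(
                dict(
                    participant_id=pid, task="effort", trial_id=t.trial_id,
                    beneficiary=t.beneficiary, d_money=None, d_shocks=None,
                    reward=t.reward, effort_level=t.effort_level,
                    is_attention_check=False, choice=rec.choice, missed=rec.missed,
                )
            )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def write_trials_csv(path, harm_by_pid: dict, effort_by_pid: dict) -> None:
    trials_frame(harm_by_pid, effort_by_pid).to_csv(path, index=False)


def read_trials_csv(path) -> tuple[dict, dict]:
    """Read a trials CSV back into per-participant ChoiceRecord lists."""
    df = pd.read_csv(path, keep_default_na=True)
    harm_by_pid: dict = {}
    effort_by_pid: dict = {}
    for row in df.itertuples(index=False):
        pid = row.participant_id
        choice = None if pd.isna(row.choice) else str(row.choice)
        missed = bool(row.missed)
        if row.task == "harm":
            trial = HarmTrial(
                int(row.trial_id), str(row.beneficiary), float(row.d_money),
                float(row.d_shocks), bool(row.is_attention_check),
            )
            harm_by_pid.setdefault(pid, []).append(ChoiceRecord(trial, choice, missed))
        elif row.task == "effort":
            level = int(row.effort_level)
            trial = EffortTrial(
                int(row.trial_id), str(row.beneficiary), int(row.reward),
                level, EFFORT_UNITS[level],
            )
            effort_by_pid.setdefault(pid, []).append(ChoiceRecord(trial, choice, missed))
        else:
            raise ValueError(f"unknown task {row.task!r}")
    return harm_by_pid, effort_by_pid


def write_traits_csv(path, traits: pd.DataFrame) -> None:
    missing = set(TRAIT_NAMES) - set(traits.columns)
    if missing:
        raise ValueError(f"traits table missing columns: {sorted(missing)}")
    traits.to_csv(path, index=False)


def read_traits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAIT_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"traits CSV missing columns: {sorted(missing)}")
    if df[list(TRAIT_NAMES)].isna().any().any():
        raise ValueError("traits CSV contains missing values")
    return df


def write_ground_truth_csv(path, ground_truth: pd.DataFrame) -> None:
    ground_truth.to_csv(path, index=False)


def read_ground_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def qc_frame(reports) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                participant_id=r.participant_id, attention_fails=r.attention_fails,
                missed_fraction=r.missed_fraction, excluded=r.excluded, reason=r.reason,
            )
            for r in reports
        ]
    )


def harm_params_frame(fits_by_pid: dict) -> pd.DataFrame:
    rows = []
    for pid, fit in fits_by_pid.items():
        p = fit.params
        rows.append(
            dict(
                participant_id=pid, kappa_self=p.kappa_self, kappa_other=p.kappa_other,
                beta_self=p.beta_self, beta_other=p.beta_other, nll=fit.nll,
                converged=fit.converged,
            )
        )
    return pd.DataFrame(rows)


def effort_params_frame(fits_by_pid: dict) -> pd.DataFrame:
    rows = []
    for pid, fit in fits_by_pid.items():
        p = fit.params
        rows.append(
            dict(
                participant_id=pid, lambda_self=p.lambda_self,
                lambda_other=p.lambda_other, beta=p.beta, nll=fit.nll,
                n_missed=fit.n_missed_excluded, converged=fit.converged,
            )
        )
    return pd.DataFrame(rows)


def stats_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                name=r.name, statistic=r.statistic, df1=r.df1, df2=r.df2,
                p=r.p_value, effect_size=r.effect_size,
            )
            for r in results
        ]
    )


def cca_coefficients_frame(result) -> pd.DataFrame:
    """Long table of weights/loadings/cross-loadings for both sets."""
    rows = []
    for setname, names, W, L, C in (
        ("traits", result.x_names, result.x_weights, result.x_loadings,
         result.x_cross_loadings),
        ("prosocial", result.y_names, result.y_weights, result.y_loadings,
         result.y_cross_loadings),
    ):
        for j, name in enumerate(names):
            for k in range(len(result.correlations)):
                rows.append(
                    dict(
                        set=setname, variable=name, function=k + 1,
                        weight=W[j, k], loading=L[j, k], cross_loading=C[j, k],
                    )
                )
    return pd.DataFrame(rows)
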