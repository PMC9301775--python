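"""Univariate statistics for the behavioral analyses.

Wraps the field-standard routines (scipy for Wilcoxon signed-rank and
Spearman, pingouin for Greenhouse–Geisser-corrected repeated-measures ANOVA)
behind a uniform :class:`TestResult`, and implements the independent-samples
Fisher-Z comparison of absolute correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df1: float | None = None
    df2: float | None = None
    effect_size: float | None = None


def wilcoxon_signed_rank(x, y, name: str = "wilcoxon") -> TestResult:
    """Paired signed-rank test, normal approximation with tie correction.

    Zero differences are dropped (Wilcoxon's rule) and no continuity
    correction is applied; the z statistic and a two-tailed p are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    nonzero = x != y
    if not nonzero.any():
        raise ValueError("all paired differences are zero")
    if nonzero.sum() < 5:
        raise ValueError("need at least 5 nonzero differences")
    res = sps.wilcoxon(
        x, y, zero_method="wilcox", correction=False, method="approx"
    )
    return TestResult(name, float(res.zstatistic), float(res.pvalue))


def spearman(x, y, name: str = "spearman") -> TestResult:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 5:
        raise ValueError("need n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    rho, p = sps.spearmanr(x, y)
    return TestResult(name, float(rho), float(p))


def fisher_z_difference(
    r1: float, n1: int, r2: float, n2: int, name: str = "fisher_z"
) -> TestResult:
    """Compare two independent correlations on their absolute values.

    z = (atanh|r1| − atanh|r2|) / sqrt(1/(n1−3) + 1/(n2−3)), two-tailed p.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(abs(r1)) - np.arctanh(abs(r2))) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(name, float(z), float(p))


def rm_anova_2xk(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str,
) -> list[TestResult]:
    """Two-way repeated-measures ANOVA with GG-corrected dfs and partial η².

    ``data`` is long-format with one row per subject × cell (cell means as
    dv, e.g. per-cell proportion of work choices).  The Greenhouse–Geisser
    correction is applied whenever a factor (or the interaction) has ≥ 3
    levels, which the fractional dfs reflect; ε = 1 for 2-level effects.
    """
    cells = data.groupby([subject, *within], observed=True)[dv].mean().unstack(within[0])
    if cells.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    aov = pg.rm_anova(
        data=data,
        dv=dv,
        within=list(within),
        subject=subject,
        correction=True,
        detailed=True,
        effsize="np2",
    )
    results = []
    for _, row in aov.iterrows():
        eps = float(row.get("eps", 1.0)) if not pd.isna(row.get("eps", 1.0)) else 1.0
        f_stat, np2 = row["F"], row["np2"]
        if pd.isna(f_stat) and abs(float(row["SS"])) < 1e-12:
            # no effect variance at all (e.g. constant dv)
            f_stat, np2, p = 0.0, 0.0, 1.0
        else:
            p = row["p_GG_corr"] if "p_GG_corr" in row and not pd.isna(row["p_GG_corr"]) else row["p_unc"]
        results.append(
            TestResult(
                name=str(row["Source"]),
                statistic=float(f_stat),
                p_value=float(p),
                df1=float(row["ddof1"]) * eps,
                df2=float(row["ddof2"]) * eps,
                effect_size=float(np2),
            )
        )
    return results


def work_proportion_cells(effort_records_by_pid, factor: str) -> pd.DataFrame:
    """Per-subject per-cell proportion of work choices for the ANOVA dv.

    ``factor`` is 'effort_level' or 'reward'; cells cross it with the
    beneficiary.  Missed trials are excluded from the denominator.
    """
    rows = []
    for pid, records in effort_records_by_pid.items():
        for rec in records:
            if rec.missed:
                continue
            rows.append(
                {
                    "subject": pid,
                    "beneficiary": rec.trial.beneficiary,
                    factor: getattr(rec.trial, factor),
                    "work": 1.0 if rec.choice == "work" else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["subject", "beneficiary", factor], observed=True)["work"]
        .mean()
        .rename("p_work")
        .reset_index()
    )
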