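import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from prosocial.stats import (
    fisher_z_difference,
    rm_anova_2xk,
    spearman,
    wilcoxon_signed_rank,
)

from oracles import wilcoxon_enumeration


class TestWilcoxon:
    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_z_matches_exact_null_moments_for_all_positive_differences(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        y = np.zeros(8)
        res = wilcoxon_signed_rank(x, y)
        w_obs, z_exact, _ = wilcoxon_enumeration(x - y)
        assert w_obs == 36.0
        assert abs(res.statistic) == pytest.approx(abs(z_exact), abs=1e-8)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_z_agrees_with_exact_enumeration_without_ties(self, n):
        # the z statistic must match the one built from the exact null
        # moments (enumerated over all 2^n sign patterns) to within 0.05
        rng = np.random.default_rng(n)
        diffs = rng.normal(0.6, 1.0, n)
        while np.any(diffs == 0) or len(np.unique(np.abs(diffs))) < n:
            diffs = rng.normal(0.6, 1.0, n)
        res = wilcoxon_signed_rank(diffs, np.zeros(n))
        _, z_exact, _ = wilcoxon_enumeration(diffs)
        assert abs(res.statistic) == pytest.approx(abs(z_exact), abs=0.05)

    def test_planted_shift_detected_at_cohort_scale(self):
        # κ_other − κ_self shift of 0.08 on an sd-0.2 difference at n=325
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            x = rng.normal(0.45, 0.25, 325)
            y = x - rng.normal(0.08, 0.20, 325)
            if wilcoxon_signed_rank(x, y).p_value < 0.05:
                hits += 1
        assert hits >= 90


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.array([0.3, 1.2, 2.9, 4.4, 7.0, 9.1])
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_ties_match_pearson_on_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).statistic == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_strictly_monotone_recoding(self, seed):
        # reverse-coding (sign flips, affine maps) cannot change |ρ|
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y).statistic
        assert spearman(x, -2.0 * y + 3.0).statistic == pytest.approx(-base, abs=1e-12)
        assert spearman(np.exp(x), y).statistic == pytest.approx(base, abs=1e-12)


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        res = fisher_z_difference(0.4, 100, 0.4, 200)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_printed_rounded_inputs(self):
        # rounded correlations 0.33 vs 0.18 at n=325 give 2.04 (unrounded
        # inputs would be needed to regenerate a slightly larger value)
        assert fisher_z_difference(0.33, 325, 0.18, 325).statistic == pytest.approx(2.04, abs=0.005)
        assert fisher_z_difference(0.3, 325, 0.18, 325).statistic == pytest.approx(1.62, abs=0.005)

    def test_absolute_values_used(self):
        a = fisher_z_difference(-0.33, 325, 0.18, 325).statistic
        b = fisher_z_difference(0.33, 325, 0.18, 325).statistic
        assert a == pytest.approx(b)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_difference(1.0, 100, 0.2, 100)


def _cells(n_subj, seed, interaction=0.0):
    """Per-subject work proportions over beneficiary × effort cells."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        base = rng.uniform(0.6, 0.9)
        for b, off in (("self", 0.0), ("other", 0.12)):
            for j, e in enumerate((30, 50, 70, 90)):
                p = np.clip(base - 0.05 * j - off - interaction * j * (b == "other"), 0.01, 0.99)
                rows.append(
                    dict(subject=s, beneficiary=b, effort=e,
                         p_work=rng.binomial(6, p) / 6.0)
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_dv_gives_zero_f(self):
        df = _cells(12, 0)
        df["p_work"] = 0.5
        for res in rm_anova_2xk(df, "p_work", ("effort", "beneficiary"), "subject"):
            assert res.statistic == 0.0
            assert res.p_value == 1.0

    def test_two_level_factor_matches_paired_t_squared(self):
        df = _cells(25, 3)
        results = {r.name: r for r in rm_anova_2xk(df, "p_work", ("effort", "beneficiary"), "subject")}
        ben = results["beneficiary"]
        means = df.groupby(["subject", "beneficiary"])["p_work"].mean().unstack()
        t = sps.ttest_rel(means["self"], means["other"]).statistic
        assert ben.df1 == 1.0  # GG ε = 1 for a 2-level factor
        assert ben.statistic == pytest.approx(t**2, rel=1e-6)

    def test_gg_correction_fractionalizes_dfs(self):
        results = rm_anova_2xk(_cells(30, 4), "p_work", ("effort", "beneficiary"), "subject")
        effort = next(r for r in results if r.name == "effort")
        assert effort.df1 < 3.0  # ε < 1 shrinks the nominal df of 3
        assert 1.0 < effort.df1

    def test_partial_eta_squared_in_unit_interval_and_affine_invariant(self):
        df = _cells(20, 5)
        res1 = rm_anova_2xk(df, "p_work", ("effort", "beneficiary"), "subject")
        df2 = df.assign(p_work=3.0 * df["p_work"] - 1.0)
        res2 = rm_anova_2xk(df2, "p_work", ("effort", "beneficiary"), "subject")
        for a, b in zip(res1, res2):
            assert 0.0 <= a.effect_size <= 1.0
            assert a.effect_size == pytest.approx(b.effect_size, rel=1e-9)

    def test_planted_interaction_detected(self):
        # other-condition work probability drops faster with effort
        hits = 0
        for s in range(100):
            df = _cells(200, 100 + s, interaction=0.035)
            results = rm_anova_2xk(df, "p_work", ("effort", "beneficiary"), "subject")
            inter = next(r for r in results if "*" in r.name)
            if inter.p_value < 0.05:
                hits += 1
        assert hits >= 90

    def test_missing_cells_rejected(self):
        df = _cells(10, 6)
        df = df[~((df.subject == 3) & (df.effort == 70) & (df.beneficiary == "self"))]
        with pytest.raises(ValueError):
            rm_anova_2xk(df, "p_work", ("effort", "beneficiary"), "subject")
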