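"""Welch t / Welch ANOVA / Games-Howell / chi-square, including the
re-analysis of the published cohort summary tables."""

import numpy as np
import pandas as pd
import pytest

from hdlatent.datasets import (
    hd_cluster_exposure_table,
    hd_cohort_summaries,
    hd_gender_counts,
)
from hdlatent.stats import (
    GroupSummary,
    chi_square,
    games_howell,
    summarize,
    welch_anova,
    welch_t,
)


class TestWelchT:
    def test_published_height_p_value(self):
        t, df, p = welch_t(*hd_cohort_summaries()["height_cm"])
        assert round(p, 3) == 0.002

    def test_published_weight_p_value(self):
        t, df, p = welch_t(*hd_cohort_summaries()["weight_kg"])
        assert round(p, 3) == 0.003

    def test_identical_groups(self):
        g = GroupSummary("g", 10, 5.0, 1.0)
        t, df, p = welch_t(g, GroupSummary("h", 10, 5.0, 1.0))
        assert t == 0.0 and p == 1.0

    def test_raw_equals_summary_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 2, 15)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(summarize(a), summarize(b))
        assert abs(t1 - t2) < 1e-12 and abs(df1 - df2) < 1e-12 and abs(p1 - p2) < 1e-12

    def test_matches_scipy_raw(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 3, 25)
        t, df, p = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_zero_variance_rejected(self):
        g = GroupSummary("g", 5, 1.0, 0.0)
        with pytest.raises(ValueError):
            welch_t(g, GroupSummary("h", 5, 1.0, 0.0))


class TestWelchAnova:
    def test_two_groups_reduce_to_welch_t(self):
        a = GroupSummary("a", 12, 1.0, 1.0)
        b = GroupSummary("b", 20, 2.0, 3.0)
        f, df1, df2, p = welch_anova([a, b])
        assert p == pytest.approx(welch_t(a, b)[2], abs=1e-10)

    def test_identical_groups_give_zero_f(self):
        g = [GroupSummary(f"g{i}", 10, 3.0, 1.0) for i in range(3)]
        f, _, _, p = welch_anova(g)
        assert f == 0.0 and p == 1.0

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        samples = [rng.normal(0, 1, 10), rng.normal(1, 2, 14), rng.normal(0.5, 0.5, 8)]
        df = pd.DataFrame({
            "y": np.concatenate(samples),
            "g": np.repeat(["a", "b", "c"], [10, 14, 8]),
        })
        ref = pg.welch_anova(dv="y", between="g", data=df)
        f, df1, df2, p = welch_anova(samples)
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        pcol = [c for c in ref.columns if c.startswith("p")][0]
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-9)

    def test_type_one_error_under_null(self):
        # 3 unequal-variance normal groups with equal means: rejection
        # rate at alpha=0.05 within 0.05 +/- 0.01.  Samples are drawn in
        # bulk and fed through the summary-statistics form (shown equal
        # to the raw form elsewhere in this suite).
        rng = np.random.default_rng(11)
        reps = 10_000
        spec = ((1.0, 12), (3.0, 18), (0.5, 9))
        draws = [rng.normal(0, s, (reps, n)) for s, n in spec]
        rejections = 0
        for r in range(reps):
            groups = [
                GroupSummary(f"g{i}", n, float(d[r].mean()), float(d[r].std(ddof=1)))
                for i, ((_, n), d) in enumerate(zip(spec, draws))
            ]
            rejections += welch_anova(groups)[3] < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) <= 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([GroupSummary("a", 5, 0.0, 1.0)])


class TestGamesHowell:
    def test_two_group_reduction_matches_welch_t(self):
        a = GroupSummary("a", 15, 0.0, 1.0)
        b = GroupSummary("b", 12, 1.0, 2.0)
        gh = games_howell([a, b])
        assert gh["p"].iloc[0] == pytest.approx(welch_t(a, b)[2], rel=1e-9)

    def test_identical_pair_p_one(self):
        g = [GroupSummary("a", 10, 1.0, 1.0), GroupSummary("b", 10, 1.0, 1.0)]
        gh = games_howell(g)
        assert gh["diff"].iloc[0] == 0.0 and gh["p"].iloc[0] == pytest.approx(1.0)

    def test_pairwise_count(self):
        gs = [GroupSummary(f"g{i}", 10, i * 1.0, 1.0) for i in range(4)]
        assert len(games_howell(gs)) == 6

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        samples = [rng.normal(0, 1, 10), rng.normal(1, 2, 14), rng.normal(0.5, 0.5, 8)]
        df = pd.DataFrame({
            "y": np.concatenate(samples),
            "g": np.repeat(["g0", "g1", "g2"], [10, 14, 8]),
        })
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        mine = games_howell(samples)
        pcol = [c for c in ref.columns if c.startswith("p")][0]
        assert np.allclose(sorted(mine["p"]), sorted(ref[pcol]), rtol=1e-6)

    def test_familywise_error_under_null(self):
        # 4-group null: probability of any pairwise rejection <= 0.06.
        # p < 0.05 iff q exceeds the studentized-range critical value at
        # the pair's Welch df; critical values are interpolated from a
        # dense df grid (they vary slowly and smoothly in df).
        from itertools import combinations

        from scipy import stats as sps

        rng = np.random.default_rng(21)
        reps = 5000
        spec = ((1.0, 10), (2.0, 14), (0.5, 8), (3.0, 12))
        k = len(spec)
        draws = [rng.normal(0, s, (reps, n)) for s, n in spec]
        means = np.stack([d.mean(axis=1) for d in draws])
        variances = np.stack([d.var(axis=1, ddof=1) for d in draws])
        ns = np.array([n for _, n in spec], dtype=float)

        df_grid = np.linspace(5.0, 30.0, 26)
        q_crit_grid = sps.studentized_range.ppf(0.95, k, df_grid)

        any_reject = np.zeros(reps, dtype=bool)
        for i, j in combinations(range(k), 2):
            vi, vj = variances[i] / ns[i], variances[j] / ns[j]
            se = np.sqrt(vi + vj)
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            q = np.abs(means[i] - means[j]) * np.sqrt(2.0) / se
            any_reject |= q > np.interp(df, df_grid, q_crit_grid)
        # anchor the fast path to the implementation on a subsample
        for r in range(0, reps, 250):
            groups = [
                GroupSummary(f"g{i}", int(ns[i]), float(means[i][r]),
                             float(np.sqrt(variances[i][r])))
                for i in range(k)
            ]
            assert (games_howell(groups)["p"] < 0.05).any() == any_reject[r]
        assert any_reject.mean() <= 0.06


class TestChiSquare:
    def test_published_cluster_exposure_table(self):
        chi2, df, p, _ = chi_square(hd_cluster_exposure_table())
        assert p < 0.001
        chi2, df, p, _ = chi_square(hd_cluster_exposure_table(include_minor=False))
        assert p < 0.001

    def test_published_gender_table_with_yates(self):
        chi2, df, p, _ = chi_square(hd_gender_counts())
        assert round(p, 3) == 0.013

    def test_proportional_margins_give_zero(self):
        table = np.outer([10, 20], [3, 7])
        chi2, df, p, _ = chi_square(table, yates=False)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        obs = np.array([[12.0, 5.0], [9.0, 14.0]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        brute = ((obs - exp) ** 2 / exp).sum()
        chi2, _, _, expected = chi_square(obs, yates=False)
        assert chi2 == pytest.approx(brute, abs=1e-10)
        assert np.allclose(expected, exp)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.array([[0, 0], [3, 4]]))

    def test_yates_default_only_for_2x2(self):
        obs22 = np.array([[10, 3], [4, 12]])
        with_y = chi_square(obs22)[0]
        without = chi_square(obs22, yates=False)[0]
        assert with_y < without  # correction shrinks the statistic
        obs32 = np.array([[10, 3], [4, 12], [6, 6]])
        assert chi_square(obs32)[0] == chi_square(obs32, yates=False)[0]


class TestPValueSanity:
    def test_p_monotone_in_statistic(self):
        ps = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            ps.append(welch_t(GroupSummary("a", 20, 0.0, 1.0),
                              GroupSummary("b", 20, delta, 1.0))[2])
        assert ps == sorted(ps, reverse=True)
        assert all(0.0 <= p <= 1.0 for p in ps)
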