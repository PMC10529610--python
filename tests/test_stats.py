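"""Group-comparison battery: t-tests, mixed ANOVA, rank tests, Holm
correction and power computations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sensolearn.stats import (
    holm_bonferroni,
    mixed_anova_2x2,
    power_mixed_interaction,
    power_two_sample_t,
    rank_tests,
    sensitivity_power,
    two_sample_tests,
)


class TestTwoSampleTests:
    def test_identical_groups(self):
        r = two_sample_tests([1.0, 2.0, 3.0] * 2,
                             ["a", "a", "a", "b", "b", "b"])
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)
        assert r.effect_size == 0.0

    def test_hand_computed_t_for_two_triples(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 9.0])
        r = two_sample_tests(np.concatenate([a, b]), ["a"] * 3 + ["b"] * 3,
                             variance_rule="student")
        sp2 = ((2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4)
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert r.statistic == pytest.approx(t_hand, abs=1e-10)
        assert r.df == 4
        d_hand = (a.mean() - b.mean()) / math.sqrt(sp2)
        assert r.effect_size == pytest.approx(d_hand, abs=1e-10)

    def test_student_and_welch_agree_under_equal_variance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 40) * (a.std(ddof=1) / 1.0)
        vals = np.concatenate([a, b])
        labels = ["a"] * 40 + ["b"] * 40
        s = two_sample_tests(vals, labels, variance_rule="student")
        w = two_sample_tests(vals, labels, variance_rule="welch")
        assert w.statistic == pytest.approx(s.statistic, abs=5e-3)
        assert w.p == pytest.approx(s.p, abs=1e-3)

    def test_welch_df_never_exceeds_student_df(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, rng.uniform(0.5, 3), rng.integers(5, 30))
            b = rng.normal(1, rng.uniform(0.5, 3), rng.integers(5, 30))
            w = two_sample_tests(np.concatenate([a, b]),
                                 ["a"] * len(a) + ["b"] * len(b),
                                 variance_rule="welch")
            assert w.df <= len(a) + len(b) - 2 + 1e-12

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 30)
        labels = ["a"] * 15 + ["b"] * 15
        r1 = two_sample_tests(vals, labels)
        r2 = two_sample_tests(3.0 * vals + 7.0, labels)
        assert r2.statistic == pytest.approx(r1.statistic, abs=1e-10)
        assert r2.p == pytest.approx(r1.p, abs=1e-12)

    def test_screen_rule_switches_to_welch(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, 20)
        b = rng.normal(0, 5.0, 20)
        r = two_sample_tests(np.concatenate([a, b]),
                             ["a"] * 20 + ["b"] * 20, variance_rule="screen")
        assert r.test == "welch_t"


def _mixed_df(groups, conds, values, subjects):
    return pd.DataFrame({"group": groups, "condition": conds,
                         "value": values, "subject": subjects})


class TestMixedAnova:
    def test_null_construction_gives_near_zero_f(self):
        """No condition effect and no interaction planted: condition
        deviations cancel across subjects within each group, so both F
        statistics are exactly zero while residual error is not."""
        rows = []
        signs = {"s0": 1.0, "s1": -1.0, "s2": 1.0, "s3": -1.0}
        for i in range(4):
            g = "a" if i < 2 else "b"
            base = (0.0 if g == "a" else 0.5) + 0.3 * i
            for c, cs in (("s", 1.0), ("v", -1.0)):
                rows.append((g, c, base + 0.4 * signs[f"s{i}"] * cs,
                             f"s{i}"))
        df = _mixed_df(*zip(*rows))
        res = mixed_anova_2x2(df, "value", "group", "condition", "subject")
        assert res["condition"].statistic == pytest.approx(0.0, abs=1e-10)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-10)

    def test_four_subject_hand_partitioning(self):
        """F values match an explicit sums-of-squares partitioning for
        one between and one within factor."""
        data = {  # subject -> (group, y_stable, y_volatile)
            "s1": ("a", 1.0, 2.0), "s2": ("a", 2.0, 4.0),
            "s3": ("b", 3.0, 3.5), "s4": ("b", 4.0, 5.5),
        }
        rows = []
        for s, (g, y1, y2) in data.items():
            rows += [(g, "stable", y1, s), (g, "volatile", y2, s)]
        df = _mixed_df(*zip(*rows))

        y = np.array([[v[1], v[2]] for v in data.values()])
        groups = np.array([v[0] for v in data.values()])
        grand = y.mean()
        subj_means = y.mean(axis=1)
        g_means = {g: y[groups == g].mean() for g in "ab"}
        c_means = y.mean(axis=0)
        ss_group = sum(2 * 2 * (g_means[g] - grand) ** 2 for g in "ab")
        ss_subj = sum(2 * (m - g_means[g]) ** 2
                      for m, g in zip(subj_means, groups))
        ss_cond = sum(4 * (c - grand) ** 2 for c in c_means)
        gc_means = {(g, c): y[groups == g][:, c_i].mean()
                    for g in "ab" for c_i, c in enumerate("sv")}
        ss_int = sum(
            2 * (gc_means[(g, c)] - g_means[g]
                 - c_means[c_i] + grand) ** 2
            for g in "ab" for c_i, c in enumerate("sv"))
        ss_total = ((y - grand) ** 2).sum()
        ss_err = ss_total - ss_group - ss_subj - ss_cond - ss_int
        f_group = (ss_group / 1) / (ss_subj / 2)
        f_cond = (ss_cond / 1) / (ss_err / 2)
        f_int = (ss_int / 1) / (ss_err / 2)

        res = mixed_anova_2x2(df, "value", "group", "condition", "subject")
        assert res["group"].statistic == pytest.approx(f_group, abs=1e-8)
        assert res["condition"].statistic == pytest.approx(f_cond, abs=1e-8)
        assert res["interaction"].statistic == pytest.approx(f_int, abs=1e-8)
        # partial eta squared per effect
        assert res["interaction"].effect_size == pytest.approx(
            ss_int / (ss_int + ss_err), abs=1e-8)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(10):
            g = "a" if i < 5 else "b"
            for c in ("s", "v"):
                rows.append((g, c, rng.normal(), f"s{i}"))
        df = _mixed_df(*zip(*rows))
        r1 = mixed_anova_2x2(df, "value", "group", "condition", "subject")
        df2 = df.assign(value=df.value + 100.0)
        r2 = mixed_anova_2x2(df2, "value", "group", "condition", "subject")
        for k in ("group", "condition", "interaction"):
            assert r2[k].statistic == pytest.approx(r1[k].statistic,
                                                    abs=1e-8)

    def test_missing_cells_listed(self):
        df = _mixed_df(["a", "a", "b"], ["s", "v", "s"],
                       [1.0, 2.0, 3.0], ["s1", "s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            mixed_anova_2x2(df, "value", "group", "condition", "subject")

    def test_planted_interaction_detected_reliably(self):
        """A group x condition interaction of f = 0.4 with groups of 17
        and 42 (repeated-measures correlation 0.5) is detected at
        p < .05 in at least 75% of 200 seeded replicates."""
        n1, n2, delta = 17, 42, 0.4
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(n1 + n2):
                g = "aut" if i < n1 else "nt"
                sign = 1.0 if g == "aut" else -1.0
                b = rng.normal(0, 1)  # subject effect -> rm corr 0.5
                for c, csign in (("s", 1.0), ("v", -1.0)):
                    mu = delta * sign * csign
                    rows.append((g, c, mu + b + rng.normal(0, 1), f"s{i}"))
            df = _mixed_df(*zip(*rows))
            res = mixed_anova_2x2(df, "value", "group", "condition",
                                  "subject")
            hits += res["interaction"].p < 0.05
        assert hits >= 150


class TestRankTests:
    def test_friedman_zero_for_identical_conditions(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["s", "s", "s", "v", "v", "v"]
        subs = ["a", "b", "c", "a", "b", "c"]
        with pytest.raises(ValueError):
            # identical in *both* conditions for every subject: all tied
            rank_tests([1, 1, 1, 1], ["s", "s", "v", "v"], "friedman",
                       subjects=["a", "b", "a", "b"])
        r = rank_tests(vals, labels, "friedman", subjects=subs)
        assert r.statistic == pytest.approx(0.0)

    def test_friedman_matches_scipy_for_three_conditions(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, (12, 3))
        stat, p = sps.friedmanchisquare(y[:, 0], y[:, 1], y[:, 2])
        vals = y.T.ravel()
        labels = np.repeat(["c1", "c2", "c3"], 12)
        subs = np.tile([f"s{i}" for i in range(12)], 3)
        r = rank_tests(vals, labels, "friedman", subjects=subs)
        assert r.statistic == pytest.approx(stat, abs=1e-10)
        assert r.p == pytest.approx(p, abs=1e-12)

    def test_mann_whitney_complete_separation(self):
        r = rank_tests([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3,
                       "mannwhitney")
        assert r.statistic == 0.0
        assert r.effect_size == pytest.approx(1.0)

    def test_kruskal_matches_brute_force_ranks_with_ties(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 6.0])
        labels = np.array(list("aabbaabbab"))
        r = rank_tests(vals, labels, "kruskal")
        ranks = sps.rankdata(vals)
        n = len(vals)
        groups = [ranks[labels == g] for g in "ab"]
        h = (12.0 / (n * (n + 1))
             * sum(len(g) * g.mean() ** 2 for g in groups)
             - 3 * (n + 1))
        _, counts = np.unique(vals, return_counts=True)
        h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
        assert r.statistic == pytest.approx(h, abs=1e-10)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.03]), [0.03])

    def test_two_p_hand_case(self):
        np.testing.assert_allclose(holm_bonferroni([0.01, 0.04]),
                                   [0.02, 0.04])

    def test_monotone_in_sorted_order_and_vs_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 12)
        adj = holm_bonferroni(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p)
        from statsmodels.stats.multitest import multipletests
        _, adj_sm, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(adj, adj_sm, atol=1e-12)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert power_two_sample_t(0.0, 29, 26) == pytest.approx(0.05,
                                                                abs=1e-9)

    def test_sensitivity_effect_sizes_match_reported_rounding(self):
        d85 = sensitivity_power("two_sample_t", (29, 26),
                                target_power=0.85)
        d50 = sensitivity_power("two_sample_t", (29, 26),
                                target_power=0.50)
        assert round(d85, 1) == 0.8
        assert round(d50, 1) == 0.5

    def test_interaction_sensitivity_matches_reported_f(self):
        f85 = sensitivity_power("mixed_interaction", (17, 42),
                                target_power=0.85)
        f50 = sensitivity_power("mixed_interaction", (17, 42),
                                target_power=0.50)
        assert round(f85, 1) == 0.4
        assert abs(f50 - 0.25) < 0.02

    def test_power_strictly_increasing_in_effect_and_n(self):
        d = np.linspace(0.1, 1.2, 12)
        p = [power_two_sample_t(x, 20, 20) for x in d]
        assert np.all(np.diff(p) > 0)
        assert power_two_sample_t(0.5, 40, 40) > power_two_sample_t(
            0.5, 20, 20)

    def test_power_curve_structure(self):
        pc = sensitivity_power("two_sample_t", (29, 26))
        assert pc.power[0] == pytest.approx(pc.alpha)
        assert np.all(np.diff(pc.power) >= 0)

    def test_simulation_oracle_for_50_percent_power(self):
        """Monte-Carlo replication of the d-at-50%-power computation:
        simulate two-sample t-tests at the analytic d and check the
        rejection rate is near 0.5."""
        d = sensitivity_power("two_sample_t", (29, 26), target_power=0.50)
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 4000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 29)
            b = rng.normal(d, 1, 26)
            _, p = sps.ttest_ind(a, b)
            rejections += p < 0.05
        se = math.sqrt(0.5 * 0.5 / n_rep)
        assert abs(rejections / n_rep - 0.50) < 4 * se

    def test_unreachable_power_raises(self):
        with pytest.raises(ValueError):
            sensitivity_power("two_sample_t", (3, 3), target_power=0.85,
                              alpha=1e-12)

    def test_gpower_convention_differs(self):
        spss = power_mixed_interaction(0.3, 17, 42, convention="spss")
        gp = power_mixed_interaction(0.3, 17, 42, convention="gpower",
                                     rm_corr=0.5)
        assert gp > spss
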