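"""Group comparison battery and sensitivity power analyses.

Covers the statistical toolkit used on fitted model parameters:
independent and Welch t-tests with Cohen's d, the 2 (group) x 2
(condition) mixed-model ANOVA with partial eta squared, Friedman /
Kruskal-Wallis / Mann-Whitney rank tests with rank-biserial effect
sizes, step-down Holm-Bonferroni correction, and exact power /
sensitivity computations from the noncentral t and F distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupComparisonResult",
    "PowerCurve",
    "two_sample_tests",
    "mixed_anova_2x2",
    "rank_tests",
    "holm_bonferroni",
    "power_two_sample_t",
    "power_mixed_interaction",
    "sensitivity_power",
]


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    effect_size: float
    effect_type: str  # "cohen_d" | "partial_eta_sq" | "rank_biserial" | ...
    p_holm: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class PowerCurve:
    design: str
    group_sizes: tuple[int, ...]
    alpha: float
    effect_sizes: np.ndarray
    power: np.ndarray
    extra: dict = field(default_factory=dict)


def _cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
           / (na + nb - 2))
    if sp2 == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / math.sqrt(sp2))


def two_sample_tests(values, labels, variance_rule: str = "screen",
                     ratio_threshold: float = 4.0) -> GroupComparisonResult:
    """Two-sample comparison of a parameter between groups.

    ``variance_rule`` selects Student's or Welch's t: "student",
    "welch", or "screen" (Welch when the group variance ratio exceeds
    ``ratio_threshold``).  Effect size is Cohen's d (pooled SD).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0 and np.mean(a) == np.mean(b):
        return GroupComparisonResult(
            "student_t", 0.0, float(len(a) + len(b) - 2), 1.0, 0.0,
            "cohen_d")
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")

    if variance_rule == "welch":
        welch = True
    elif variance_rule == "student":
        welch = False
    elif variance_rule == "screen":
        lo, hi = sorted([va, vb])
        welch = lo == 0 or hi / lo > ratio_threshold
    else:
        raise ValueError(f"unknown variance rule {variance_rule!r}")

    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1)
            + (vb / len(b)) ** 2 / (len(b) - 1))
        name = "welch_t"
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        df = float(len(a) + len(b) - 2)
        name = "student_t"
    return GroupComparisonResult(
        name, float(t), float(df), float(p), _cohen_d(a, b), "cohen_d",
        extra={"groups": list(map(str, groups)), "welch": welch},
    )


def mixed_anova_2x2(data: pd.DataFrame, dv: str, between: str,
                    within: str, subject: str) -> dict[str, GroupComparisonResult]:
    """2 x 2 mixed-model ANOVA (one between-subject and one
    within-subject factor) with partial eta squared per effect.

    Each subject must contribute both within-factor levels; missing
    cells raise with the offending subjects listed.  Uses the standard
    sums-of-squares partitioning (pingouin); with the balanced
    within-subject design the SS types coincide.
    """
    counts = data.groupby(subject)[within].nunique()
    n_within = data[within].nunique()
    bad = sorted(counts.index[counts < n_within].astype(str))
    if bad:
        raise ValueError(f"subjects missing within-factor cells: {bad}")
    import pingouin as pg

    aov = pg.mixed_anova(data=data, dv=dv, between=between, within=within,
                         subject=subject, effsize="np2")
    out = {}
    keymap = {between: "group", within: "condition",
              "Interaction": "interaction"}
    for _, row in aov.iterrows():
        key = keymap.get(row["Source"], str(row["Source"]))
        out[key] = GroupComparisonResult(
            test=f"mixed_anova_{key}", statistic=float(row["F"]),
            df=(float(row["DF1"]), float(row["DF2"])),
            p=float(row["p_unc"]), effect_size=float(row["np2"]),
            effect_type="partial_eta_sq",
        )
    return out


def _rank_biserial(u_stat: float, n1: int, n2: int) -> float:
    return 1.0 - 2.0 * u_stat / (n1 * n2)


def _friedman(table: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square on an n x k (subjects x
    conditions) table; valid for k >= 2 repeated measures."""
    n, k = table.shape
    if k < 2:
        raise ValueError("friedman requires at least 2 conditions")
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction: within-subject tied ranks shrink the denominator
    tie_sum = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0:
        # every row fully tied: no evidence of a condition effect
        return 0.0, 1.0
    q /= correction
    return q, float(stats.chi2.sf(q, k - 1))


def rank_tests(values, labels, design: str,
               subjects=None) -> GroupComparisonResult:
    """Non-parametric tests: ``design`` selects Friedman (paired
    conditions), Kruskal-Wallis (grouped), or Mann-Whitney (two
    groups, with normal-approximation z and rank-biserial r)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if np.all(values == values[0]):
        raise ValueError("all observations tied; rank tests undefined")

    if design == "friedman":
        if subjects is None:
            raise ValueError("friedman requires subject pairing")
        wide = pd.DataFrame(
            {"v": values, "l": labels, "s": np.asarray(subjects)}
        ).pivot(index="s", columns="l", values="v")
        if wide.isna().any().any():
            raise ValueError("friedman requires complete pairing")
        stat, p = _friedman(wide.to_numpy())
        return GroupComparisonResult(
            "friedman", float(stat), float(len(wide.columns) - 1), float(p),
            float("nan"), "none")
    if design == "kruskal":
        samples = [values[labels == g] for g in levels]
        stat, p = stats.kruskal(*samples)
        return GroupComparisonResult(
            "kruskal_wallis", float(stat), float(len(levels) - 1), float(p),
            float("nan"), "none")
    if design == "mannwhitney":
        if len(levels) != 2:
            raise ValueError("mann-whitney requires exactly 2 groups")
        a, b = values[labels == levels[0]], values[labels == levels[1]]
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        n1, n2 = len(a), len(b)
        mu = n1 * n2 / 2.0
        # tie-corrected normal approximation
        _, tie_counts = np.unique(values, return_counts=True)
        n = n1 + n2
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
        sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        z = (u - mu) / sigma if sigma > 0 else 0.0
        return GroupComparisonResult(
            "mann_whitney", float(u), None, float(p),
            abs(_rank_biserial(float(u), n1, n2)), "rank_biserial",
            extra={"z": float(z)})
    raise ValueError(f"unknown design {design!r}")


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


def power_two_sample_t(d: float, n1: int, n2: int,
                       alpha: float = 0.05) -> float:
    """Exact two-tailed power of the two-sample t-test via the
    noncentral t distribution."""
    if min(n1, n2) < 2:
        raise ValueError("group sizes must be at least 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def power_mixed_interaction(f: float, n1: int, n2: int, alpha: float = 0.05,
                            n_within: int = 2, rm_corr: float = 0.5,
                            convention: str = "spss") -> float:
    """Power of the group x condition interaction in a two-group mixed
    ANOVA, via the noncentral F distribution.

    ``convention`` sets how the effect size f maps to the noncentrality:
    "spss" takes f as already incorporating the repeated-measures
    correlation (lambda = f^2 * N); "gpower" applies the correction
    lambda = f^2 * N * m / (1 - rm_corr) for m within levels.
    """
    N = n1 + n2
    df1 = (2 - 1) * (n_within - 1)
    df2 = (N - 2) * (n_within - 1)
    if convention == "spss":
        lam = f * f * N
    elif convention == "gpower":
        lam = f * f * N * n_within / (1.0 - rm_corr)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def sensitivity_power(design: str, group_sizes: tuple[int, int],
                      alpha: float = 0.05, target_power: float | None = None,
                      effect_grid=None, rm_corr: float = 0.5,
                      convention: str = "spss"):
    """Sensitivity analysis: power curve over effect sizes, or the
    effect size achieving ``target_power``.

    ``design``: "two_sample_t" (effect size d) or "mixed_interaction"
    (effect size f).  With ``target_power`` set, returns the minimal
    detectable effect; otherwise returns a :class:`PowerCurve` over
    ``effect_grid``.
    """
    n1, n2 = group_sizes
    if design == "two_sample_t":
        fn = lambda es: power_two_sample_t(es, n1, n2, alpha)
    elif design == "mixed_interaction":
        fn = lambda es: power_mixed_interaction(
            es, n1, n2, alpha, rm_corr=rm_corr, convention=convention)
    else:
        raise ValueError(f"unknown design {design!r}")

    if target_power is not None:
        if not 0 < target_power < 1 or target_power <= alpha:
            raise ValueError("target power must lie in (alpha, 1)")
        hi = 0.5
        while fn(hi) < target_power:
            hi *= 2.0
            if hi > 100:
                raise ValueError("requested power unreachable")
        return float(optimize.brentq(
            lambda es: fn(es) - target_power, 1e-9, hi, xtol=1e-8))

    if effect_grid is None:
        effect_grid = np.linspace(0.0, 1.5, 76)
    grid = np.asarray(effect_grid, dtype=float)
    power = np.array([fn(es) if es > 0 else alpha for es in grid])
    return PowerCurve(design=design, group_sizes=(n1, n2), alpha=alpha,
                      effect_sizes=grid, power=power,
                      extra={"rm_corr": rm_corr, "convention": convention})
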