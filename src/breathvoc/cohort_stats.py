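"""Subject-characteristics statistics for the cohort summary tables.

Percentages are computed from subgroup counts with half-up rounding.
Continuous group comparisons are gated on normality: only when every group
passes both the Shapiro-Wilk and the Lilliefors test at the gate level does
the parametric branch run (t-test for two groups, one-way ANOVA for more);
otherwise the rank-based branch (Mann-Whitney U / Kruskal-Wallis).
Categorical associations use Fisher's exact test (two-sided by the
point-probability rule) for 2x2 tables with any expected cell below 5, and
the chi-square test (with continuity correction for 2x2) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors


@dataclass
class SubgroupTable:
    """Counts and continuous summaries for one cohort group (train/validation)."""

    group_label: str
    categories: list  # e.g. ["A-AD", "NA", "NA-AD", "NA-NAD"]
    n: dict  # category -> subgroup size
    counts: dict = field(default_factory=dict)  # (variable, category) -> count
    continuous: dict = field(default_factory=dict)  # (variable, category) -> values

    def __post_init__(self):
        if "NA" in self.n and "NA-AD" in self.n and "NA-NAD" in self.n:
            if self.n["NA"] != self.n["NA-AD"] + self.n["NA-NAD"]:
                raise ValueError(
                    "NA subgroup must be the union of NA-AD and NA-NAD"
                )
        for (var, cat), c in self.counts.items():
            if c > self.n.get(cat, c):
                raise ValueError(f"count for {var!r}/{cat!r} exceeds subgroup size")

    def percentage(self, variable: str, category: str) -> int:
        return subgroup_percentage(self.counts[(variable, category)], self.n[category])


@dataclass
class GroupTestResult:
    variable: str
    test_used: str  # t, anova, mann_whitney, kruskal_wallis, chi_square, fisher
    p_value: float
    gate: dict = field(default_factory=dict)


def subgroup_percentage(count: int, n: int) -> int:
    """Integer percentage, rounded half-up (72/186 -> 39)."""
    if n <= 0:
        raise ValueError("subgroup size must be positive")
    if not 0 <= count <= n:
        raise ValueError("count must satisfy 0 <= count <= n")
    return int(np.floor(100.0 * count / n + 0.5))


def normality_test(x, method: str = "shapiro_wilk") -> float:
    """Normality p-value by Shapiro-Wilk or Lilliefors (n >= 4)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("normality tests need n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality test degenerate")
    if method == "shapiro_wilk":
        return float(stats.shapiro(x).pvalue)
    if method == "lilliefors":
        _, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
        return float(p)
    raise ValueError(f"unknown method {method!r}")


def compare_continuous(groups, alpha_gate: float = 0.05) -> GroupTestResult:
    """Normality-gated comparison of >= 2 continuous groups.

    The parametric branch requires *every* group to pass *both* normality
    tests at ``alpha_gate`` (a conservative AND-rule); the decision trail is
    recorded in ``gate``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 4:
            raise ValueError("each group needs n >= 4")
    gate = {}
    normal = True
    for i, g in enumerate(groups):
        p_sw = normality_test(g, "shapiro_wilk")
        p_lf = normality_test(g, "lilliefors")
        gate[f"group{i}"] = {"shapiro_wilk": p_sw, "lilliefors": p_lf}
        if p_sw < alpha_gate or p_lf < alpha_gate:
            normal = False
    if normal:
        if len(groups) == 2:
            test, p = "t", stats.ttest_ind(groups[0], groups[1]).pvalue
        else:
            test, p = "anova", stats.f_oneway(*groups).pvalue
    else:
        if len(groups) == 2:
            test, p = "mann_whitney", stats.mannwhitneyu(
                groups[0], groups[1], alternative="two-sided"
            ).pvalue
        else:
            test, p = "kruskal_wallis", stats.kruskal(*groups).pvalue
    return GroupTestResult("", test, float(p), gate)


def contingency_test(table) -> GroupTestResult:
    """Association test on an r x c count table.

    Fisher's exact test (two-sided, point-probability rule) for 2x2 tables
    with any expected count below 5; chi-square otherwise (continuity
    correction applied to 2x2 tables).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2-d array of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    gate = {"min_expected": float(expected.min())}
    if t.shape == (2, 2) and expected.min() < 5:
        _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return GroupTestResult("", "fisher", float(p), gate)
    correction = t.shape == (2, 2)
    res = stats.chi2_contingency(t, correction=correction)
    return GroupTestResult("", "chi_square", float(res.pvalue), gate)
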