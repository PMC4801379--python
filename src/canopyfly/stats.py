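"""Statistical comparisons for the simulation experiments.

The decision rule mirrors common ecological practice: each group is checked
for normality with the Shapiro-Wilk test at alpha = 0.05; normal data go to
parametric tests (Welch's t for independent pairs, paired t, one-way ANOVA
with a Tukey HSD post hoc), non-normal data to their rank-based counterparts
(Mann-Whitney U, Wilcoxon signed-rank, Kruskal-Wallis with a
Bonferroni-adjusted Dunn post hoc). Count designs with empty regions use
one-way or two-way chi-square tests on visit tallies. Multi-group results
carry compact letter displays so that groups sharing no letter differ at the
chosen alpha.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05

DESIGNS = ("independent", "paired", "oneway", "counts_oneway", "counts_twoway")


@dataclass
class TestResult:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    df: Optional[float]
    pvalue: float
    letters: Optional[Dict[str, str]] = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.pvalue) and self.pvalue < ALPHA)


def _is_constant(x: np.ndarray) -> bool:
    return bool(np.ptp(x) == 0)


def _all_normal(groups: Sequence[np.ndarray], alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk gate; constant groups bypass to nonparametric with a warning."""
    for g in groups:
        if _is_constant(g):
            warnings.warn(
                "constant group encountered; normality gate bypassed to a "
                "nonparametric test",
                stacklevel=3,
            )
            return False
        if sps.shapiro(g).pvalue < alpha:
            return False
    return True


def dunn_posthoc(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise Dunn test p-values (tie-corrected, Bonferroni-adjusted).

    Returns a symmetric (k, k) matrix with 1.0 on the diagonal.
    """
    k = len(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    sizes = np.array([len(g) for g in groups])
    bounds = np.cumsum(sizes)
    mean_ranks = [
        ranks[(0 if i == 0 else bounds[i - 1]) : bounds[i]].mean() for i in range(k)
    ]
    m = k * (k - 1) // 2
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        pmat[i, j] = pmat[j, i] = p
    return pmat


def compact_letter_display(
    labels: Sequence[str],
    pmatrix: np.ndarray,
    means: Sequence[float],
    alpha: float = ALPHA,
) -> Dict[str, str]:
    """Compact letter display from a pairwise p-value matrix.

    Insert-and-absorb construction: groups whose pairwise comparison is
    significant never share a letter; non-significant pairs share at least
    one. Letter order follows descending group mean.
    """
    k = len(labels)
    columns = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if pmatrix[i, j] < alpha:
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                a, b = set(col), set(col)
                a.discard(j)
                b.discard(i)
                for new in (a, b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # absorb: drop columns that are subsets of others
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: -max(means[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, col in zip(alphabet, columns):
        for g in sorted(col):
            out[labels[g]] += letter
    return out


def choose_and_run_test(
    groups,
    design: str = "independent",
    labels: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> TestResult:
    """Apply the normality-gated test-selection rule to replicate-level data.

    ``design`` is one of ``independent`` (two groups, Welch t / Mann-Whitney),
    ``paired`` (two matched groups, paired t / Wilcoxon signed-rank),
    ``oneway`` (three or more groups, ANOVA + Tukey / Kruskal-Wallis + Dunn;
    letters attached), ``counts_oneway`` (one vector of region counts,
    chi-square goodness of fit) or ``counts_twoway`` (contingency table
    chi-square). All-zero count tables yield a degenerate result instead of
    an error.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")

    if design == "counts_oneway":
        counts = np.asarray(groups, dtype=float).ravel()
        if counts.sum() == 0:
            return TestResult("chi-square (one-way)", float("nan"), None, float("nan"),
                              note="degenerate: all counts zero")
        res = sps.chisquare(counts)
        return TestResult("chi-square (one-way)", float(res.statistic),
                          float(len(counts) - 1), float(res.pvalue))

    if design == "counts_twoway":
        table = np.asarray(groups, dtype=float)
        if table.sum() == 0:
            return TestResult("chi-square (two-way)", float("nan"), None, float("nan"),
                              note="degenerate: all counts zero")
        res = sps.chi2_contingency(table)
        return TestResult("chi-square (two-way)", float(res.statistic),
                          float(res.dof), float(res.pvalue))

    data = [np.asarray(g, dtype=float) for g in groups]
    for g in data:
        if len(g) < 3:
            raise ValueError("each group needs at least 3 values")

    if design == "paired":
        if len(data) != 2 or len(data[0]) != len(data[1]):
            raise ValueError("paired design needs two groups of equal length")
        diff = data[0] - data[1]
        if _is_constant(diff):
            if diff[0] == 0:
                return TestResult("paired t-test", 0.0, float(len(diff) - 1), 1.0,
                                  note="degenerate: zero differences")
            return TestResult("paired t-test", math.copysign(math.inf, diff[0]),
                              float(len(diff) - 1), 0.0,
                              note="degenerate: constant non-zero difference")
        if _all_normal([diff], alpha):
            res = sps.ttest_rel(data[0], data[1])
            return TestResult("paired t-test", float(res.statistic),
                              float(len(diff) - 1), float(res.pvalue))
        res = sps.wilcoxon(data[0], data[1])
        return TestResult("Wilcoxon signed-rank", float(res.statistic), None,
                          float(res.pvalue))

    if design == "independent":
        if len(data) != 2:
            raise ValueError("independent design needs exactly two groups")
        if _all_normal(data, alpha):
            res = sps.ttest_ind(data[0], data[1], equal_var=False)
            return TestResult("Welch t-test", float(res.statistic),
                              float(res.df), float(res.pvalue))
        res = sps.mannwhitneyu(data[0], data[1], alternative="two-sided")
        return TestResult("Mann-Whitney U", float(res.statistic), None,
                          float(res.pvalue))

    # oneway, >= 3 groups
    if len(data) < 3:
        raise ValueError("oneway design needs at least three groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(data))]
    means = [float(g.mean()) for g in data]
    if _all_normal(data, alpha):
        res = sps.f_oneway(*data)
        tukey = sps.tukey_hsd(*data)
        k = len(data)
        pmat = np.ones((k, k))
        for i, j in itertools.combinations(range(k), 2):
            pmat[i, j] = pmat[j, i] = tukey.pvalue[i, j]
        letters = compact_letter_display(labels, pmat, means, alpha)
        return TestResult("one-way ANOVA + Tukey", float(res.statistic),
                          float(len(data) - 1), float(res.pvalue), letters=letters)
    res = sps.kruskal(*data)
    pmat = dunn_posthoc(data)
    letters = compact_letter_display(labels, pmat, means, alpha)
    return TestResult("Kruskal-Wallis + Dunn", float(res.statistic),
                      float(len(data) - 1), float(res.pvalue), letters=letters)
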