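"""Categorical and rank tests for cohort comparisons.

Fisher's exact test (two-sided by the "probabilities at most that of the
observed table" rule, the convention of R's fisher.test), the exact
binomial McNemar test on discordant pairs, and the Wilcoxon rank-sum test
(exact enumeration for small tie-free samples, normal approximation with
continuity and tie correction otherwise). The computations delegate to
scipy.stats; this module fixes the conventions and the degenerate-input
behavior.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = ["TestResult", "fisher_exact", "mcnemar_exact", "wilcoxon_rank_sum"]


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value, "method": self.method}


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    A table with an empty row or column carries no association information
    and returns p = 1 by convention. The statistic is the sample odds
    ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact requires a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("fisher_exact requires at least one observation")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(statistic=float("nan"), p_value=1.0, method="fisher-exact")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(min(p, 1.0)), method="fisher-exact")


def mcnemar_exact(n_discordant_01: int, n_discordant_10: int) -> TestResult:
    """Exact two-sided McNemar test on discordant pair counts.

    Under the null of marginal homogeneity the discordant pairs are
    Binomial(n01 + n10, 1/2); zero discordance gives p = 1 by convention.
    The statistic reported is the smaller discordant count.
    """
    n01, n10 = int(n_discordant_01), int(n_discordant_10)
    if n01 < 0 or n10 < 0:
        raise ValueError("discordant counts must be non-negative")
    n = n01 + n10
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="mcnemar-exact")
    p = stats.binomtest(min(n01, n10), n, 0.5, alternative="two-sided").pvalue
    return TestResult(statistic=float(min(n01, n10)), p_value=float(min(p, 1.0)), method="mcnemar-exact")


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when both samples have at most 10 observations
    and the pooled sample is tie-free; otherwise the normal approximation
    with continuity correction and midrank tie correction. The statistic
    is the Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method=f"wilcoxon-rank-sum-{method}")
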