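"""Cohort statistics: gated location tests, factorial ANOVA with Tukey
post-hoc comparisons, Bonferroni correction, Pearson correlation, and an
exact multi-set intersection test.

The intersection test generalizes the hypergeometric two-set overlap test
to k sets: under independent uniform draws of the observed set sizes from
a background of N elements, the distribution of the k-way intersection
size is built by iterated hypergeometric convolution — the overlap of the
(j+1)-th set with the current j-set intersection of size x is
hypergeometric(N, x, n_{j+1}).  The reported p-value is the upper tail
P(X >= observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    n: tuple[int, ...]
    p_adjusted: float | None = None

    def adjusted(self, m: int) -> "TestResult":
        from dataclasses import replace

        return replace(self, p_adjusted=min(1.0, self.p * m))


def welch_t(x, y) -> TestResult:
    """Two-sided Welch t test (Satterthwaite df).

    Two zero-variance groups with equal means return p = 1 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "welch", (len(x), len(y)))
        return TestResult(np.inf, 0.0, "welch", (len(x), len(y)))
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch",
                      (len(x), len(y)))


def _wilcoxon_rank_sum(x, y) -> TestResult:
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon",
                      (len(x), len(y)))


def location_test_gated(x, y, alpha: float = 0.05,
                        large_n: int = 30) -> TestResult:
    """Welch t unless Shapiro-Wilk rejects normality in either group.

    Groups with n >= ``large_n`` are exempt from the gate (large-sample
    normality of the mean); constant groups cannot be tested for
    normality and are treated as non-normal.  The chosen method is
    recorded on the result.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    if np.var(x) == 0 and np.var(y) == 0 and x.mean() == y.mean():
        return TestResult(0.0, 1.0, "degenerate", (len(x), len(y)))

    def _non_normal(v):
        if len(v) >= large_n:
            return False
        if np.ptp(v) == 0:
            return True
        if len(v) < 3:
            return False  # Shapiro-Wilk undefined; no evidence against
        return sps.shapiro(v).pvalue < alpha

    if _non_normal(x) or _non_normal(y):
        return _wilcoxon_rank_sum(x, y)
    return welch_t(x, y)


def bonferroni(ps, m: int | None = None):
    """min(1, p * m); ``m`` defaults to the family size len(ps)."""
    ps = list(ps)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError("family size m smaller than number of p-values")
    return [min(1.0, p * m) for p in ps]


def pearson(x, y) -> dict:
    """Pearson r with the two-sided t-transform p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": None, "p": None, "n": len(x), "undefined": True}
    res = sps.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(x)}


# ---------------------------------------------------------------------------
# Factorial ANOVA
# ---------------------------------------------------------------------------

def anova_factorial(table: pd.DataFrame, response: str, factors,
                    interactions: bool = False,
                    tukey_factors=None, alpha: float = 0.05) -> dict:
    """Type-II factorial ANOVA with Tukey HSD post-hoc comparisons.

    ``factors`` are column names treated as categorical; the default
    model has main effects only.  Returns the ANOVA table, per-factor
    p-values, Tukey pairwise results for the requested factors, and the
    main-effects linear-model coefficients with their t-test p-values.
    Raises on rank-deficient designs, naming the aliased terms.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    factors = list(factors)
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    op = " * " if interactions else " + "
    formula = f"{response} ~ " + op.join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=table).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < \
            model.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design for factors {factors}; aliased terms "
            "cannot be separated (e.g. a factor nested in another)"
        )
    anova = sm.stats.anova_lm(model, typ=2)
    pvals = {}
    for f in factors:
        row = f"C({f})"
        if row in anova.index:
            pvals[f] = float(anova.loc[row, "PR(>F)"])
    tukey = {}
    for f in tukey_factors or []:
        res = pairwise_tukeyhsd(table[response], table[f].astype(str),
                                alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:],
                             columns=res.summary().data[0])
        tukey[f] = frame
    coefs = pd.DataFrame(
        {"coef": model.params, "p": model.pvalues, "t": model.tvalues}
    )
    return {
        "anova": anova,
        "p_values": pvals,
        "tukey": tukey,
        "coefficients": coefs,
        "model": model,
    }


# ---------------------------------------------------------------------------
# Multi-set intersection test
# ---------------------------------------------------------------------------

def intersection_distribution(sizes, N: int) -> np.ndarray:
    """Exact pmf of the k-way intersection size for independent uniform
    draws of the given set sizes from a background of N elements."""
    sizes = list(sizes)
    if any(n > N for n in sizes):
        raise ValueError("set size exceeds background size")
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    nmax = min(sizes)
    # the running intersection starts as the first set itself; its size
    # can exceed nmax until the smallest set has entered the chain
    first = sizes[0]
    support = np.zeros(first + 1)
    support[first] = 1.0
    for n in sizes[1:]:
        new = np.zeros(min(len(support) - 1, n) + 1)
        xs = np.flatnonzero(support > 0)
        for x in xs:
            hi = min(x, n)
            ks = np.arange(0, hi + 1)
            new[: hi + 1] += support[x] * sps.hypergeom.pmf(ks, N, x, n)
        support = new
    out = np.zeros(nmax + 1)
    out[: len(support)] = support[: nmax + 1]
    return out


def multiset_intersection_test(sets, N: int) -> dict:
    """Exact upper-tail test of the observed k-way intersection size.

    ``sets`` is a sequence of element collections drawn from a common
    background of ``N`` elements.  Returns the observed overlap, its
    expectation ``N * prod(n_i / N)``, and ``p = P(X >= observed)`` under
    the iterated-hypergeometric null.
    """
    sets = [set(s) for s in sets]
    sizes = [len(s) for s in sets]
    if any(n > N for n in sizes):
        raise ValueError("set size exceeds background size")
    observed = len(set.intersection(*sets))
    expected = N * float(np.prod([n / N for n in sizes]))
    pmf = intersection_distribution(sizes, N)
    p = float(pmf[observed:].sum())
    return {
        "observed_overlap": observed,
        "expected": expected,
        "p": min(1.0, p),
        "sizes": sizes,
        "N": N,
        "pmf": pmf,
    }
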