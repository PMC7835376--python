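"""Statistical test kernels used by the enrichment battery.

Thin, explicitly-named wrappers around scipy.stats so that every test used
anywhere in the package has a single auditable definition:

* two-sided Fisher's exact test on a 2x2 table,
* chi-squared test of independence with Yates's continuity correction,
* two-sided exact binomial test (minimum-likelihood two-sided convention),
* two-sided Mann-Whitney U and Welch t tests for group comparisons,
* Bonferroni adjustment, capped at 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = [
    "fisher_two_sided",
    "chisq_yates",
    "binomial_two_sided",
    "mann_whitney_two_sided",
    "welch_t_two_sided",
    "bonferroni",
]


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    return t


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p: hypergeometric tail sum over tables with
    probability <= the observed table's."""
    t = _as_table(table)
    return float(_st.fisher_exact(t, alternative="two-sided")[1])


def chisq_yates(table) -> float:
    """Chi-squared test with Yates's correction for continuity (df=1).

    Degenerate tables (a zero row or column margin) carry no evidence of
    association and return p = 1.
    """
    t = _as_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(_st.chi2_contingency(t, correction=True)[1])


def binomial_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value: sum of P(j) over all outcomes j with
    P(j) <= P(k) under Binomial(n, p)."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("null probability must be in [0, 1]")
    return float(_st.binomtest(k, n, p, alternative="two-sided").pvalue)


def mann_whitney_two_sided(x, y) -> float:
    return float(_st.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def welch_t_two_sided(x, y) -> float:
    return float(_st.ttest_ind(x, y, equal_var=False).pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p for a family of m tests, capped at 1."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * m)
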