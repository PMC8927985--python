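"""Statistics for the modeling arm: Spearman rank correlation, 2x2
contingency tests with the chi-squared/Fisher selection rule, and the
Mann-Whitney U test for class-stratified comparisons.

These wrap scipy.stats; the expected-count rule (Fisher's exact test
whenever any expected cell count is below 5, Pearson chi-squared without
continuity correction otherwise) is applied here.  No multiple-testing
correction is applied anywhere in the pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


def spearman(x, y):
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p).  p uses the large-sample t approximation.  Zero
    variance in either vector makes the correlation undefined: (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise StatsError("need two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def contingency_test(table):
    """2x2 association test with automatic method selection.

    Pearson chi-squared (no continuity correction) when all expected counts
    are >= 5, Fisher's exact test (two-sided, hypergeometric) otherwise.
    Returns (statistic, p_value, method)."""
    tab = np.asarray(table)
    if tab.shape != (2, 2) or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if np.any(tab != np.round(tab)) or np.any(tab < 0):
            raise StatsError("table must hold non-negative integer counts")
        tab = tab.astype(int)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise StatsError("empty margin: association undefined")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if expected.min() < 5:
        odds, p = sps.fisher_exact(tab, alternative="two-sided")
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), float(p), "chi2"


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U (rank-sum) test; exact for small untied
    samples, normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both groups must be non-empty")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(u), float(p)


def median_iqr(values):
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), (float("nan"), float("nan"))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), (float(q1), float(q3))
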