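"""Rank tests and correlation for follicle/tissue group comparisons.

Two-sided throughout.  Small samples get exact p-values (full enumeration of
the rank-permutation null), larger ones the normal approximation with tie
and continuity corrections; the cutoffs (total n <= 12 for Mann-Whitney, <=
15 nonzero pairs for Wilcoxon) keep the exact path sub-second and are
configurable per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

DEFAULT_ALPHA = 0.05


@dataclass
class ComparisonResult:
    test: str                 # mann_whitney | wilcoxon_signed_rank | pearson
    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str               # exact | normal_approx | t_dist
    alpha: float = DEFAULT_ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


def mann_whitney_u(x, y, exact_max_n: int = 12, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Two-sided Mann-Whitney U for two independent samples.

    Exact p by enumeration of rank assignments when the combined sample has
    at most ``exact_max_n`` observations and no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    use_exact = no_ties and (x.size + y.size) <= exact_max_n
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if use_exact else "asymptotic",
                           use_continuity=True)
    return ComparisonResult(test="mann_whitney", statistic=float(res.statistic),
                            p_two_sided=float(min(res.pvalue, 1.0)),
                            n1=x.size, n2=y.size,
                            method="exact" if use_exact else "normal_approx",
                            alpha=alpha)


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 15,
                         alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples (or a single
    sample of differences).  Zero differences are dropped; W is the smaller
    signed-rank sum.  Exact p by enumeration of sign patterns for at most
    ``exact_max_n`` nonzero pairs without tied magnitudes."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size == 0:
        raise InsufficientDataError("need at least one pair")
    nz = d[d != 0]
    if nz.size == 0:
        return ComparisonResult(test="wilcoxon_signed_rank", statistic=0.0,
                                p_two_sided=1.0, n1=d.size, n2=d.size,
                                method="degenerate", alpha=alpha, degenerate=True)
    no_ties = np.unique(np.abs(nz)).size == nz.size
    use_exact = no_ties and nz.size <= exact_max_n
    res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                       correction=True, method="exact" if use_exact else "approx")
    return ComparisonResult(test="wilcoxon_signed_rank", statistic=float(res.statistic),
                            p_two_sided=float(min(res.pvalue, 1.0)),
                            n1=d.size, n2=d.size,
                            method="exact" if use_exact else "normal_approx",
                            alpha=alpha)


def pearson_r(x, y, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Pearson correlation with two-sided p from the t distribution on
    n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    res = sps.pearsonr(x, y)
    return ComparisonResult(test="pearson", statistic=float(res.statistic),
                            p_two_sided=float(res.pvalue), n1=x.size, n2=y.size,
                            method="t_dist", alpha=alpha)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (optional; per-comparison reporting is the
    default and no correction is applied unless asked for)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
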