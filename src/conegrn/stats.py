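"""Statistical primitives shared by all pipeline stages.

Wraps scipy for the classical tests and keeps the conventions used
throughout the pipeline in one place: the Wilcoxon rank-sum marker test
(exact for small tie-free samples, normal approximation with tie and
continuity correction otherwise), Benjamini-Hochberg adjustment wherever an
FDR or "adjusted p" threshold is applied, the upper-tail hypergeometric
enrichment test computed in log space, Pearson correlation with its
t-distribution p-value, the paired t-test used for element-count
comparisons, and pseudocounted log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import PipelineError

EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise PipelineError("bad-statistic", "non-finite statistic")
        if not (0.0 <= self.p_value <= 1.0):
            raise PipelineError("bad-p", f"p={self.p_value} outside [0,1]")


@dataclass(frozen=True)
class FoldChange:
    log2fc: float
    mean_a: float
    mean_b: float


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when n_a + n_b <= 20 and there are no ties;
    normal approximation with tie correction and continuity correction
    otherwise. Statistic is the Mann-Whitney U of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PipelineError("empty-group", "both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        # all values identical: no evidence either way
        return TestResult(statistic=a.size * b.size / 2.0, p_value=1.0)
    if a.size + b.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise PipelineError("bad-p", "p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    # guard against 1-ulp rounding in p * n / rank at the top rank
    return np.maximum(out, p)


def hypergeom_upper_tail(k, n_draws, K_success, N_pop):
    """P(X >= k) for X ~ Hypergeometric(N_pop, K_success, n_draws), log-space.

    Broadcasts over array arguments; scalar inputs return a float.
    """
    k, n_draws, K_success, N_pop = (
        np.asarray(x) for x in (k, n_draws, K_success, N_pop)
    )
    scalar = k.ndim == 0 and n_draws.ndim == 0 and K_success.ndim == 0 and N_pop.ndim == 0
    if (
        np.any(k < 0) or np.any(k > n_draws) or np.any(n_draws > N_pop)
        or np.any(K_success < 0) or np.any(K_success > N_pop)
    ):
        raise PipelineError("bad-counts", "require 0 <= k <= n <= N and 0 <= K <= N")
    with np.errstate(divide="ignore"):
        logp = sps.hypergeom.logsf(k - 1, N_pop, K_success, n_draws)
    out = np.minimum(1.0, np.exp(logp))
    out = np.where(k == 0, 1.0, out)
    return float(out) if scalar else out


def pearson(x, y) -> TestResult:
    """Pearson r with its two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PipelineError("bad-input", "need equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PipelineError("constant-input", "zero variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(np.clip(r, -1.0, 1.0)), p_value=float(p))


def paired_t(x, y) -> TestResult:
    """One-sample t-test on paired differences x - y, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise PipelineError("bad-input", "need equal lengths >= 2")
    d = x - y
    if np.ptp(d) == 0:
        # includes x == y and constant non-zero differences (sd = 0)
        raise PipelineError("degenerate", "paired differences have zero variance")
    t, p = sps.ttest_rel(x, y)
    return TestResult(statistic=float(t), p_value=float(p))


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 1.0) -> FoldChange:
    """log2((mean_a + eps) / (mean_b + eps)) with pseudocount eps > 0."""
    if mean_a < 0 or mean_b < 0:
        raise PipelineError("negative-mean", "means must be >= 0")
    if pseudocount <= 0:
        raise PipelineError("bad-pseudocount", "pseudocount must be > 0")
    lfc = float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))
    return FoldChange(log2fc=lfc, mean_a=float(mean_a), mean_b=float(mean_b))
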