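"""Normality-gated location tests with effect sizes.

Every comparison first checks normality with the Shapiro-Wilk test at
alpha = 0.05.  One-sample comparisons against zero (lag times) use Student's
t-test when the sample is normal and the one-sample Wilcoxon signed-rank test
otherwise; two-sample comparisons use the independent t-test when both samples
are normal and the Mann-Whitney U-test otherwise.  Effect size is Cohen's d:
mean/SD for the one-sample case, mean difference over the pooled SD for the
two-sample case (no small-sample correction, no multiple-testing adjustment;
an optional Holm step is available for the report stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss


@dataclass
class TestReport:
    metric: str
    test_used: str             # "t", "wilcoxon", "mann-whitney", "degenerate"
    statistic: float
    p: float
    d: float                   # Cohen's d
    n: tuple[int, ...]
    normal: tuple[bool, ...]   # Shapiro-Wilk verdict per sample


def cohens_d_one_sample(values: np.ndarray) -> float:
    """d = mean / SD (sample SD, ddof=1)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    return float(v.mean() / sd) if sd > 0 else np.nan


def cohens_d_two_sample(a: np.ndarray, b: np.ndarray) -> float:
    """d = (mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else np.nan


def _is_normal(v: np.ndarray, alpha: float) -> bool:
    if np.ptp(v) == 0:
        return False
    return ss.shapiro(v).pvalue >= alpha


def one_sample_vs_zero(values: np.ndarray, alpha: float = 0.05,
                       metric: str = "") -> TestReport:
    """Shapiro-gated one-sample test of a location against zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(v) == 0:
        return TestReport(metric, "degenerate", np.nan, np.nan,
                          np.nan, (v.size,), (False,))
    normal = _is_normal(v, alpha)
    if normal:
        res = ss.ttest_1samp(v, 0.0)
        used = "t"
    else:
        res = ss.wilcoxon(v)
        used = "wilcoxon"
    return TestReport(metric, used, float(res.statistic), float(res.pvalue),
                      cohens_d_one_sample(v), (v.size,), (normal,))


def two_sample(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
               metric: str = "") -> TestReport:
    """Shapiro-gated independent two-sample test (a vs b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return TestReport(metric, "degenerate", np.nan, np.nan, np.nan,
                          (a.size, b.size), (False, False))
    norm_a, norm_b = _is_normal(a, alpha), _is_normal(b, alpha)
    if norm_a and norm_b:
        res = ss.ttest_ind(a, b)
        used = "t"
    else:
        res = ss.mannwhitneyu(a, b, alternative="two-sided")
        used = "mann-whitney"
    return TestReport(metric, used, float(res.statistic), float(res.pvalue),
                      cohens_d_two_sample(a, b), (a.size, b.size),
                      (norm_a, norm_b))


def holm_correction(reports: list[TestReport]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order (optional step)."""
    p = np.array([r.p for r in reports], dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
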