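"""Group-level statistics on raw samples or printed summary tables.

Published group summaries usually print mean +/- SEM and n; the two-sample
t statistic can be reconstructed exactly from those numbers by recovering
SD = SEM * sqrt(n) and pooling variances, which this module does alongside
Welch and paired variants, Pearson correlation, the two-sample
Kolmogorov-Smirnov test, and multiple-testing adjustment (Bonferroni and
the Benjamini-Krieger-Yekutieli adaptive two-stage linear step-up FDR
procedure).  All p-values are two-sided.

Note that rounding of printed SEMs propagates roughly +/-0.02 into a
reconstructed t value; comparisons against printed statistics should allow
for that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "AdjustResult",
    "pooled_t_from_summary",
    "welch_t_from_summary",
    "pooled_t",
    "paired_t",
    "pearson",
    "ks_two_sample",
    "adjust_p",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary: mean +/- SEM with sample size."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.sem < 0:
            raise ValueError(f"group {self.label!r}: sem must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: str


def _t_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Equal-variance two-sample t reconstructed from mean/SEM/n summaries."""
    sd_a, sd_b = a.sd, b.sd
    df = a.n + b.n - 2
    s2 = ((a.n - 1) * sd_a**2 + (b.n - 1) * sd_b**2) / df
    t = (a.mean - b.mean) / np.sqrt(s2 * (1.0 / a.n + 1.0 / b.n))
    return TestResult(float(t), float(df), _t_p(t, df), "pooled_t_summary")


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Welch's unequal-variance t from summaries (Satterthwaite df)."""
    va, vb = a.sem**2, b.sem**2  # variance of each mean
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(float(t), float(df), _t_p(t, df), "welch_t_summary")


def pooled_t(x, y) -> TestResult:
    """Equal-variance two-sample t on raw samples (matches the summary route)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = GroupSummary("x", float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), x.size)
    b = GroupSummary("y", float(y.mean()), float(y.std(ddof=1) / np.sqrt(y.size)), y.size)
    res = pooled_t_from_summary(a, b)
    return TestResult(res.statistic, res.df, res.p, "pooled_t")


def paired_t(x, y) -> TestResult:
    """Paired two-sample t (t of the within-pair differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    return TestResult(float(t), float(df), _t_p(t, df), "paired_t")


def pearson(x, y) -> tuple[float, float, float]:
    """Product-moment correlation; returns ``(r, r2, p)`` with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r * r), float(p)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: sup ECDF difference and asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class AdjustResult:
    rejected: np.ndarray  # boolean flags per hypothesis
    adjusted: np.ndarray | None  # adjusted p-values (Bonferroni only)
    method: str
    q: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def _bh_stepup(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection flags at ``level``."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = level * np.arange(1, m + 1) / m
    passed = np.nonzero(p[order] <= thresh)[0]
    rejected = np.zeros(m, dtype=bool)
    if passed.size:
        rejected[order[: passed[-1] + 1]] = True
    return rejected


def adjust_p(pvalues, method: str = "bky_two_stage", q: float = 0.05) -> AdjustResult:
    """Multiple-testing adjustment.

    ``bonferroni``
        Adjusted p = min(1, m * p); reject where adjusted <= q.
    ``bky_two_stage``
        Adaptive two-stage linear step-up FDR control: stage 1 runs BH at
        q' = q / (1 + q) giving r1 rejections; the null count is estimated
        as m0_hat = m - r1; if r1 = 0 nothing is rejected, if m0_hat = 0
        everything is, otherwise stage 2 runs BH at level q' * m / m0_hat.
        Rejection flags define the procedure; no adjusted values are
        returned.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        adjusted = np.minimum(1.0, m * p)
        return AdjustResult(adjusted <= q, adjusted, "bonferroni", q)
    if method == "bky_two_stage":
        q1 = q / (1.0 + q)
        stage1 = _bh_stepup(p, q1)
        r1 = int(stage1.sum())
        if r1 == 0:
            rejected = np.zeros(m, dtype=bool)
        elif r1 == m:
            rejected = np.ones(m, dtype=bool)
        else:
            m0_hat = m - r1
            rejected = _bh_stepup(p, q1 * m / m0_hat)
        return AdjustResult(rejected, None, "bky_two_stage", q)
    raise ValueError("method must be 'bonferroni' or 'bky_two_stage'")
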