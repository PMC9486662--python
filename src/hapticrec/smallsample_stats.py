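"""Nonparametric and summary-statistics tests for very small cohorts.

Every statistic reported by the downstream analyses is computed here, so the
rest of the package contains no test arithmetic of its own.  The collection
covers rank tests (Kruskal-Wallis, Mann-Whitney with a normal-approximation
z, Friedman), two-sample t and one-way ANOVA recomputed from published
group summaries (mean, SD, n), the Liebermeister quasi-exact measure for
2x2 tables used in voxel-based lesion-symptom mapping, and Bonferroni
correction.

Conventions
-----------
* Mann-Whitney z uses the tie-corrected normal approximation without
  continuity correction (with n = 7 per group the approximation matches the
  published one-decimal z values either way).
* The default two-sample t-test pools variances; Welch's variant is
  available via ``pooled=False``.
* The Liebermeister measure increments both concordant cells of the 2x2
  table by one before taking the one-sided hypergeometric tail, the
  convention of the lesion-mapping literature; the plain one-sided Fisher
  p is always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "kruskal_wallis",
    "mann_whitney_z",
    "friedman",
    "t_from_summary",
    "anova_from_summary",
    "liebermeister",
    "bonferroni",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published group summary: label, sample size, mean and SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: SD must be >= 0")

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(label=label, n=arr.size, mean=float(arr.mean()),
                   sd=float(arr.std(ddof=1)))


@dataclass
class TestResult:
    """Outcome of a statistical test.

    ``statistic_name`` identifies the reported quantity (H, U, z, chi2_F, t,
    F, p_liebermeister); ``extras`` carries secondary quantities such as the
    Mann-Whitney U accompanying a z, or the Fisher p accompanying a
    Liebermeister p.
    """

    statistic_name: str
    value: float
    p: float
    dof: float | None = None
    correction: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p}")


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis one-way analysis of variance on ranks.

    H is tie-corrected; the p-value comes from the chi-square approximation
    with k - 1 degrees of freedom.  Two completely rank-separated groups of
    seven yield H = 9.8 regardless of the actual values.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 1 for a in arrs):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = _rank(pooled)
    h = 0.0
    offset = 0
    for a in arrs:
        r = ranks[offset:offset + a.size]
        h += r.sum() ** 2 / a.size
        offset += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (n_total ** 3 - n_total) if n_total > 1 else 1.0
    if denom <= 0:  # all values identical
        h = 0.0
    else:
        h /= denom
    dof = len(arrs) - 1
    p = float(stats.chi2.sf(h, dof))
    return TestResult("H", float(h), p, dof=dof)


def mann_whitney_z(a: Sequence[float], b: Sequence[float],
                   two_tailed: bool = True,
                   tie_correction: bool = True) -> TestResult:
    """Mann-Whitney U with a normal-approximation z.

    The z statistic is signed: positive when sample ``a`` tends to exceed
    sample ``b``.  No continuity correction is applied.  The variance is
    tie-corrected by default; ``tie_correction=False`` gives the plain
    approximation, which matches historically reported z values for data
    with heavily tied (e.g. floor-level) scores.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rank(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie = _tie_term(pooled) if tie_correction else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        z = 0.0
    else:
        z = (u - mu) / np.sqrt(var)
    if two_tailed:
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = float(stats.norm.sf(z))
    p = min(p, 1.0)
    return TestResult("z", float(z), p, extras={"U": u})


def friedman(table: np.ndarray) -> TestResult:
    """Friedman chi-square for a subjects x conditions table.

    Values are ranked within each subject (average ranks for ties); the
    statistic is tie-corrected.  With n subjects showing an identical
    ordering over k conditions the statistic attains its maximum
    n * (k - 1) * 12 / ... , e.g. 21 for n = 7, k = 4.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    ranks = np.apply_along_axis(_rank, 1, x)
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_sums ** 2))
    chi2 = 12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)
    ties = sum(_tie_term(row) for row in x)
    c = 1.0 - ties / (n * k * (k ** 2 - 1))
    if c <= 0:  # every row constant
        chi2 = 0.0
    else:
        chi2 /= c
    dof = k - 1
    p = float(stats.chi2.sf(chi2, dof))
    return TestResult("chi2_F", float(chi2), p, dof=dof)


def t_from_summary(g1: GroupSummary, g2: GroupSummary,
                   pooled: bool = True) -> TestResult:
    """Two-sample t-test recomputed from (mean, SD, n) summaries."""
    if g1.sd == 0 and g2.sd == 0:
        raise ValueError("both SDs are zero: t undefined")
    if pooled:
        dof = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2) / dof
        se = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    else:
        v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
        se = np.sqrt(v1 + v2)
        dof = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    t = (g1.mean - g2.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return TestResult("t", float(t), p, dof=float(dof),
                      extras={"variant": "pooled" if pooled else "welch"})


def anova_from_summary(groups: Sequence[GroupSummary]) -> TestResult:
    """One-way ANOVA F recomputed from per-group (mean, SD, n) summaries."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    k = len(groups)
    grand = float(np.sum(ns * means) / n_total)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("F", 0.0, 1.0, dof=float(df_b))
        return TestResult("F", float("inf"), 0.0, dof=float(df_b),
                          extras={"degenerate": "zero within-group variance"})
    ms_within = ss_within / df_w
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_b, df_w))
    return TestResult("F", float(f), p, dof=float(df_b),
                      extras={"dof_within": float(df_w)})


def liebermeister(a: int, b: int, c: int, d: int) -> TestResult:
    """Liebermeister quasi-exact measure for a 2x2 table [[a, b], [c, d]].

    The one-sided p toward positive association (large ``a`` and ``d``) is
    the hypergeometric upper tail of the table with both concordant cells
    incremented by one.  The plain one-sided Fisher p for the original table
    is returned in ``extras['p_fisher']``.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"cell {name} must be a non-negative integer")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    # Fisher one-sided: P(X >= a) with X ~ Hypergeom(N, a+c, a+b)
    p_fisher = float(stats.hypergeom.sf(a - 1, n_total, a + c, a + b))
    # Liebermeister: increment concordant cells -> P(X >= a+1)
    p_lieb = float(stats.hypergeom.sf(a, n_total + 2, a + c + 1, a + b + 1))
    p_lieb = min(p_lieb, 1.0)
    return TestResult("p_liebermeister", p_lieb, p_lieb,
                      extras={"p_fisher": min(p_fisher, 1.0)})


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: p * m clipped at 1.

    ``m`` defaults to the number of tests and must not be smaller.
    """
    ps = [float(p) for p in p_values]
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"m = {m} smaller than the number of tests ({len(ps)})")
    return [min(p * m, 1.0) for p in ps]
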