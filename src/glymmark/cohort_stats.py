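"""Group-comparison and correlation layer for cohort tables.

All two-sample and k-sample location tests are computable either from
raw per-subject data or directly from printed group summaries
(n, mean, sd) — the published tables therefore serve as exact fixtures.
The homoscedasticity gate reproduces the published mix of pooled and
Welch t statistics: a two-sided F-ratio test on the group variances at
alpha = 0.05 selects the pooled statistic when equality of variances is
not rejected, Welch-Satterthwaite otherwise (a Levene-type gate would
need raw data).  Shapiro-Wilk normality screening is available for raw
data.  Partial correlation is computed by residualizing both variables
on the covariates (with intercept) and correlating the residuals, with
a t-based p at n - 2 - k degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sst


@dataclass
class GroupSummary:
    """Printed summary of one group: n, mean, sd."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label}: n must be >= 2")
        if self.sd <= 0:
            raise ValueError(f"group {self.label}: sd must be positive")


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    pairwise: dict[str, float] | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class PartialCorrResult:
    r: float
    df: int
    p: float
    covariates: list[str] = field(default_factory=list)


def summarize(x: Sequence[float], label: str = "") -> GroupSummary:
    """GroupSummary from raw data (sample sd, ddof=1)."""
    x = np.asarray(x, dtype=np.float64)
    return GroupSummary(label=label, n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


def _as_summary(g, label: str = "") -> GroupSummary:
    return g if isinstance(g, GroupSummary) else summarize(g, label)


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def variance_gate(a, b, alpha: float = 0.05) -> str:
    """``"pooled"`` or ``"welch"`` by a two-sided F-ratio variance test."""
    a, b = _as_summary(a, "a"), _as_summary(b, "b")
    f = a.sd**2 / b.sd**2
    p = 2.0 * min(
        sst.f.cdf(f, a.n - 1, b.n - 1),
        sst.f.sf(f, a.n - 1, b.n - 1),
    )
    return "welch" if p < alpha else "pooled"


def t_test(a, b, variant: str = "auto", alpha_gate: float = 0.05) -> TestResult:
    """Two-sample t from raw data or summaries.

    ``variant="auto"`` applies the homoscedasticity gate; ``"pooled"``
    and ``"welch"`` force the classical or Satterthwaite statistic.
    """
    a, b = _as_summary(a, "a"), _as_summary(b, "b")
    if variant == "auto":
        variant = variance_gate(a, b, alpha_gate)
    va, vb = a.sd**2, b.sd**2
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        name = "t_pooled"
    elif variant == "welch":
        se = np.sqrt(va / a.n + vb / b.n)
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
        name = "t_welch"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (a.mean - b.mean) / se
    p = 2.0 * sst.t.sf(abs(t), df)
    return TestResult(test_name=name, statistic=float(t), df=(float(df),), p=float(p))


def anova_oneway(groups: Sequence, bonferroni_pairs: bool = False) -> TestResult:
    """One-way ANOVA from raw data or summaries.

    F = MS_between / MS_within with df (k-1, N-k), exactly computable
    from (n, mean, sd) per group.  With ``bonferroni_pairs`` the result
    carries pooled-variance pairwise t-tests corrected by the number of
    pairs.
    """
    gs = [_as_summary(g, f"g{i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    N = sum(g.n for g in gs)
    k = len(gs)
    grand = sum(g.n * g.mean for g in gs) / N
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in gs)
    ss_within = sum((g.n - 1) * g.sd**2 for g in gs)
    df1, df2 = k - 1, N - k
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sst.f.sf(f, df1, df2))
    result = TestResult(
        test_name="anova_f", statistic=float(f), df=(float(df1), float(df2)), p=p
    )
    if bonferroni_pairs:
        raw = {}
        for i in range(k):
            for j in range(i + 1, k):
                tr = t_test(gs[i], gs[j], variant="pooled")
                raw[f"{gs[i].label} vs {gs[j].label}"] = tr.p
        m = len(raw)
        result.pairwise = dict(zip(raw, bonferroni_pairwise(list(raw.values()), m)))
    return result


def chi_square(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=np.float64)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sst.chi2_contingency(table, correction=False)
    return TestResult(
        test_name="chi_square",
        statistic=float(res.statistic),
        df=(float(res.dof),),
        p=float(res.pvalue),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank-based Kruskal-Wallis H with tie correction (raw data only)."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        raise ValueError("H undefined: all values tied across all groups")
    h, p = sst.kruskal(*arrays)
    return TestResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        df=(float(len(arrays) - 1),),
        p=float(p),
    )


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    w, p = sst.shapiro(np.asarray(x, dtype=np.float64))
    return TestResult(test_name="shapiro_wilk", statistic=float(w), df=(), p=float(p))


def bonferroni_pairwise(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """p_adj = min(1, m * p); m defaults to the number of comparisons."""
    pvals = list(pvals)
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(pvals)
    return [min(1.0, m * p) for p in pvals]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
) -> PartialCorrResult:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on [1, covariates] by least
    squares; the p-value is t-based with df = n - 2 - #covariates.
    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariate rows must match n")
        k = covariates.shape[1]
        Z = np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero residual variance")
    r = float((rx * ry).sum() / denom)
    df = n - 2 - k
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        p = 0.0
    else:
        t = r_ * np.sqrt(df / (1.0 - r_**2))
        p = float(2.0 * sst.t.sf(abs(t), df))
    return PartialCorrResult(
        r=r, df=df, p=p, covariates=list(covariate_names or [])[:k] if k else []
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided t-based p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    res = sst.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
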