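"""The study's statistical battery, computable from raw data or from
published summary statistics.

Group comparisons follow the reported analysis plan: Shapiro–Wilk normality
gate per group, pooled-variance Student t for normal variables (Welch
available by flag), Mann–Whitney U otherwise, Pearson chi-square for
categorical tables, Spearman rank correlation for metric-vs-scale
associations, Cohen's d effect sizes, and a noncentral-t power calculation
for the two-sample design.  No multiple-testing correction is applied, which
report headers state explicitly.

Star rendering follows the table footnote convention: ``**`` for p < 0.01,
``***`` for p < 0.001.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError, SchemaError

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "shapiro_normality",
    "t_test_summary",
    "t_test_raw",
    "mann_whitney",
    "chi_square",
    "spearman",
    "cohens_d",
    "required_sample_size",
    "compare_groups",
    "correlate_with_scale",
]

#: Largest sample size for which the Spearman p-value is computed by exact
#: enumeration of all permutations (8! = 40320 is still instantaneous).
SPEARMAN_EXACT_MAX_N = 8

#: Largest per-group size for which the Mann-Whitney p-value uses the exact
#: distribution (no ties); beyond this the tie-corrected normal
#: approximation is used.
MANN_WHITNEY_EXACT_MAX_N = 20


def stars(p: float) -> str:
    """Footnote star rendering: ** for p < 0.01, *** for p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


@dataclass(frozen=True)
class GroupComparisonResult:
    """One variable's two-group comparison."""

    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    test: str  # "pooled-t" | "welch-t" | "mann-whitney"
    statistic: float
    df: float | None
    p: float
    cohens_d: float | None

    @property
    def stars(self) -> str:
        return stars(self.p)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman association between one metric and one scale."""

    pair: tuple[str, str]
    rho: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        return stars(self.p)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p.  Requires 3 <= n <= 5000 and a non-constant sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"Shapiro–Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise InsufficientDataError("Shapiro–Wilk is unreliable beyond n = 5000")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro–Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def t_test_summary(
    m1: float, sd1: float, n1: int,
    m2: float, sd2: float, n2: int,
    variant: str = "pooled",
    variable: str = "",
) -> GroupComparisonResult:
    """Two-sample t test from group summaries (mean, SD, n).

    ``variant="pooled"`` is Student's equal-variance test
    (sp^2 = ((n1-1)sd1^2 + (n2-1)sd2^2) / (n1+n2-2), df = n1+n2-2);
    ``variant="welch"`` uses the Welch–Satterthwaite correction.  The p-value
    is two-sided.  This is how published tables (means ± SDs per group) are
    re-tested without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("t test needs n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise DegenerateInputError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both groups have zero variance")
    if variant == "pooled":
        sp = _pooled_sd(sd1, n1, sd2, n2)
        se = sp * math.sqrt(1 / n1 + 1 / n2)
        df: float = n1 + n2 - 2
        test = "pooled-t"
    elif variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        test = "welch-t"
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = (m1 - m2) / se
    p = 2 * sps.t.sf(abs(t), df)
    d = cohens_d(m1, sd1, n1, m2, sd2, n2)
    return GroupComparisonResult(
        variable=variable, mean1=m1, sd1=sd1, n1=n1, mean2=m2, sd2=sd2, n2=n2,
        test=test, statistic=float(t), df=float(df), p=float(min(p, 1.0)), cohens_d=d,
    )


def t_test_raw(x, y, variant: str = "pooled", variable: str = "") -> GroupComparisonResult:
    """Two-sample t test from raw samples.

    Computed directly with :func:`scipy.stats.ttest_ind`; by construction it
    agrees with :func:`t_test_summary` applied to the samples' own means,
    SDs and sizes (a cross-check the test suite enforces to 1e-12).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("t test needs n >= 2 in each group")
    sd1, sd2 = float(x.std(ddof=1)), float(y.std(ddof=1))
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both samples are constant")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    d = cohens_d(float(x.mean()), sd1, x.size, float(y.mean()), sd2, y.size)
    return GroupComparisonResult(
        variable=variable,
        mean1=float(x.mean()), sd1=sd1, n1=int(x.size),
        mean2=float(y.mean()), sd2=sd2, n2=int(y.size),
        test="pooled-t" if variant == "pooled" else "welch-t",
        statistic=float(res.statistic), df=float(res.df),
        p=float(res.pvalue), cohens_d=d,
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (U of the first sample, p).

    Exact null distribution for small tie-free samples (both n <= 20);
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InsufficientDataError("Mann–Whitney needs at least one value per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (max(x.size, y.size) <= MANN_WHITNEY_EXACT_MAX_N) and not has_ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x k count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise DegenerateInputError("chi-square needs a 2-D count table")
    if (tab < 0).any():
        raise DegenerateInputError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise DegenerateInputError("chi-square undefined with a zero marginal")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def _spearman_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    """Pearson correlation of midranks."""
    xd = xr - xr.mean()
    yd = yr - yr.mean()
    denom = math.sqrt(float((xd**2).sum() * (yd**2).sum()))
    if denom == 0:
        raise DegenerateInputError("Spearman undefined for a constant input")
    return float((xd * yd).sum() / denom)


def spearman(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    For n <= 8 the p-value is exact — the proportion of the n! pairings with
    |rho| at least the observed — which is the appropriate null at the tiny
    sample sizes where the t approximation breaks down.  For larger n the
    standard t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"Spearman needs n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Spearman undefined for a constant input")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = _spearman_rho(xr, yr)
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(yr)))
        xd = xr - xr.mean()
        yd = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((xd**2).sum() * (yd**2).sum(axis=1))
        rhos = (yd @ xd) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        res = sps.spearmanr(x, y)
        p = float(res.pvalue)
    return CorrelationResult(pair=pair, rho=rho, p=p, n=n)


def cohens_d(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """Standardised mean difference (m1 - m2) / sp with pooled sp."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("Cohen's d needs n >= 2 in each group")
    sp = _pooled_sd(sd1, n1, sd2, n2)
    if sp == 0:
        raise DegenerateInputError("pooled SD is zero; d undefined")
    return float((m1 - m2) / sp)


def power_two_sample_t(
    d: float, n_per_group: int, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Power of a two-sample pooled t test via the noncentral t distribution.

    df = 2n - 2, noncentrality ncp = d * sqrt(n / 2).
    """
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2)
    if two_sided:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tcrit, df, ncp))


def required_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    two_sided: bool = True,
    max_n: int = 10_000_000,
) -> int:
    """Smallest per-group n whose two-sample pooled t test attains ``power``.

    Power is computed exactly from the noncentral t distribution; n is found
    by bisection over a doubling bracket.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    lo, hi = 2, 2
    while power_two_sample_t(d, hi, alpha, two_sided) < power:
        hi *= 2
        if hi > max_n:
            raise RuntimeError(f"required n exceeds {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_sample_t(d, mid, alpha, two_sided) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)


# ---------------------------------------------------------------------------
# roster-level operations
# ---------------------------------------------------------------------------


def compare_groups(
    roster: pd.DataFrame,
    variables: list[str],
    group_a: str,
    group_b: str,
    normality_alpha: float = 0.05,
    group_col: str = "group",
) -> list[GroupComparisonResult]:
    """Per-variable two-group comparison with a Shapiro normality gate.

    Each group's values are Shapiro–Wilk tested at ``normality_alpha``; the
    pooled t test is used when both groups pass, the Mann–Whitney U test
    otherwise (also when a group is constant or too small for the gate).
    """
    if group_col not in roster.columns:
        raise SchemaError(f"roster lacks a {group_col!r} column")
    for g in (group_a, group_b):
        if g not in set(roster[group_col]):
            raise SchemaError(f"group {g!r} absent from roster")
    results = []
    for var in variables:
        if var not in roster.columns:
            raise SchemaError(f"variable {var!r} absent from roster")
        a = roster.loc[roster[group_col] == group_a, var].dropna().to_numpy(dtype=float)
        b = roster.loc[roster[group_col] == group_b, var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError(f"variable {var!r}: need n >= 2 per group")
        normal = True
        for sample in (a, b):
            try:
                _, p_sw = shapiro_normality(sample)
                normal &= p_sw > normality_alpha
            except (DegenerateInputError, InsufficientDataError):
                normal = False
        if normal:
            res = t_test_raw(a, b, variant="pooled", variable=var)
        else:
            u, p = mann_whitney(a, b)
            try:
                d = cohens_d(float(a.mean()), float(a.std(ddof=1)), a.size,
                             float(b.mean()), float(b.std(ddof=1)), b.size)
            except DegenerateInputError:
                d = None
            res = GroupComparisonResult(
                variable=var,
                mean1=float(a.mean()), sd1=float(a.std(ddof=1)), n1=int(a.size),
                mean2=float(b.mean()), sd2=float(b.std(ddof=1)), n2=int(b.size),
                test="mann-whitney", statistic=float(u), df=None, p=float(p), cohens_d=d,
            )
        results.append(res)
    return results


def correlate_with_scale(
    roster: pd.DataFrame,
    metric_vars: list[str],
    scale_var: str,
) -> list[CorrelationResult]:
    """Spearman correlation of each metric with a clinical scale.

    Missing values are deleted listwise per pair; the surviving n is
    reported.  Fewer than 3 pairs raises :class:`InsufficientDataError`.
    """
    if scale_var not in roster.columns:
        raise SchemaError(f"scale variable {scale_var!r} absent from roster")
    out = []
    for var in metric_vars:
        if var not in roster.columns:
            raise SchemaError(f"metric variable {var!r} absent from roster")
        sub = roster[[var, scale_var]].dropna()
        if len(sub) < 3:
            raise InsufficientDataError(
                f"fewer than 3 complete pairs for ({var}, {scale_var})"
            )
        out.append(
            spearman(sub[var].to_numpy(float), sub[scale_var].to_numpy(float),
                     pair=(var, scale_var))
        )
    return out
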