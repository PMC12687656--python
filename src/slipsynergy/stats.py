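"""Statistical toolbox for the early- vs late-training comparisons.

Conventions: normality by a Lilliefors-corrected Kolmogorov-Smirnov test
(parameters estimated from the sample); paired comparisons by dependent-
samples t-test with the paired Cohen's d (dz = mean(d)/sd(d)) as effect
size; synergy dimensionality by paired Wilcoxon signed-rank (zeros dropped,
exact p for small n); trial-level training effects by one-way within-subject
(repeated-measures) ANOVA without sphericity correction; synergy-vector
similarity by Pearson r, with the critical value at a given alpha obtained
from the t distribution (r* = t*/sqrt(t*^2 + df); alpha = 0.01 at df = 6
gives the 0.83 similarity threshold). No multiple-comparison correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sct
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "StatsResult",
    "ks_normality",
    "paired_t",
    "wilcoxon_signed_rank",
    "rm_anova",
    "pearson_r",
    "critical_r",
]


@dataclass
class StatsResult:
    test: str                       # ks | paired_t | wilcoxon | rm_anova | pearson
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size_d: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _paired(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    return x - y


def ks_normality(x: Sequence[float]) -> StatsResult:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Uses the Lilliefors correction (the naive KS p-value is anti-conservative
    when mean and sd come from the sample).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("constant sample: normality test undefined")
    d, p = lilliefors(x, dist="norm")
    return StatsResult("ks", float(d), (float(x.size),), float(min(p, 1.0)), n=x.size)


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatsResult:
    """Dependent-samples t-test with paired Cohen's d (dz)."""
    d = _paired(x, y)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return StatsResult("paired_t", 0.0, (float(n - 1),), 1.0,
                               effect_size_d=0.0, n=n)
        raise ValueError("degenerate pairs: zero variance with nonzero mean difference")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sct.t.sf(abs(t), n - 1)
    return StatsResult("paired_t", float(t), (float(n - 1),), float(p),
                       effect_size_d=float(mean / sd), n=n)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> StatsResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences are mid-ranked;
    the p-value is exact for up to 25 nonzero tie-free pairs and a normal
    approximation with continuity correction otherwise. If every difference
    is zero the statistic is 0 with p = 1 by convention.
    """
    d = _paired(x, y)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatsResult("wilcoxon", 0.0, (0.0,), 1.0, n=0)
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    if method == "exact":
        res = sct.wilcoxon(d, method="exact")
    else:
        res = sct.wilcoxon(d, method="approx", correction=True)
    return StatsResult("wilcoxon", float(res.statistic), (float(n),),
                       float(res.pvalue), n=n)


def rm_anova(values: np.ndarray) -> StatsResult:
    """One-way within-subject ANOVA on a participants x conditions table.

    F = MS_condition / MS_(condition x subject) with df (c-1, (c-1)(n-1)),
    no sphericity correction. Missing cells are not imputed.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be participants x conditions")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing cells are not supported")
    n, c = values.shape
    if n < 2 or c < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = c * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = c - 1
    df_err = (c - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ms_cond == 0 else np.inf
        p = 1.0 if ms_cond == 0 else 0.0
    else:
        f = ms_cond / ms_err
        p = float(sct.f.sf(f, df_cond, df_err))
    return StatsResult("rm_anova", float(f), (float(df_cond), float(df_err)),
                       float(p), n=n)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> StatsResult:
    """Pearson correlation with df = n - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    res = sct.pearsonr(a, b)
    return StatsResult("pearson", float(res.statistic), (float(a.size - 2),),
                       float(res.pvalue), n=a.size)


def critical_r(alpha: float, df: int) -> float:
    """Two-tailed critical Pearson r at significance ``alpha``.

    r* = t*/sqrt(t*^2 + df) with t* the (1 - alpha/2) Student-t quantile.
    At alpha = 0.01, df = 6 this gives the 0.83 synergy-similarity
    threshold.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    t_star = sct.t.ppf(1 - alpha / 2.0, df)
    return float(t_star / np.sqrt(t_star ** 2 + df))
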