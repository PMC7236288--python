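"""Empirical distributions and heteroscedastic group comparisons.

Abundance distributions across genomes are summarised as empirical
cumulative distribution functions. Group comparisons use the
Brown-Forsythe (median-centred Levene) test for variance homogeneity and,
because repeat-abundance variances are typically unequal, Welch's
heteroscedastic one-way ANOVA with Welch-Satterthwaite denominator degrees
of freedom.

Species do not contribute statistically independent data points (shared
ancestry inflates the effective sample size), so every test result also
carries a conservative p value recomputed with the denominator degrees of
freedom halved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ECDF:
    """Empirical CDF: F(x) = proportion of sample values <= x."""

    values: np.ndarray       # sorted sample values
    proportions: np.ndarray  # (# <= value) / n at each sorted value

    def __call__(self, x) -> np.ndarray | float:
        idx = np.searchsorted(self.values, np.asarray(x), side="right")
        out = idx / len(self.values)
        return float(out) if np.isscalar(x) else out


def ecdf(values: Sequence[float]) -> ECDF:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    n = v.size
    return ECDF(values=v, proportions=np.arange(1, n + 1) / n)


@dataclass(frozen=True)
class TestResult:
    """An F-type test outcome, with the halved-df conservative p alongside."""

    name: str
    statistic: float
    df_num: float
    df_denom: float
    p_value: float
    p_value_halved_df: Optional[float] = None

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df_num": self.df_num,
            "df_denom": self.df_denom,
            "p_value": self.p_value,
            "p_value_halved_df": self.p_value_halved_df,
        }


def _as_groups(groups: Sequence[Sequence[float]], min_n: int = 2):
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrs):
        if a.size < min_n:
            raise ValueError(f"group {i} has {a.size} values; need >= {min_n}")
    return arrs


def levene_test(
    groups: Sequence[Sequence[float]], center: str = "median"
) -> TestResult:
    """Variance-homogeneity test (Levene; median centring = Brown-Forsythe).

    The statistic is the one-way ANOVA F on absolute deviations from the
    per-group centre, on (g-1, N-g) degrees of freedom.
    """
    arrs = _as_groups(groups)
    stat, p = sps.levene(*arrs, center=center)
    g = len(arrs)
    n_total = sum(a.size for a in arrs)
    return TestResult(
        name=f"levene({center})",
        statistic=float(stat),
        df_num=float(g - 1),
        df_denom=float(n_total - g),
        p_value=float(p),
    )


def welch_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    With group sizes n_i, means m_i, variances s_i^2 and weights
    w_i = n_i / s_i^2, W = sum w_i, the statistic is

        F = [sum w_i (m_i - m_w)^2 / (g - 1)]
            / [1 + 2 (g - 2) / (g^2 - 1) * A]

    where m_w = sum w_i m_i / W, A = sum (1 - w_i/W)^2 / (n_i - 1), and the
    denominator degrees of freedom are (g^2 - 1) / (3 A). For two groups
    this reduces to the square of Welch's t with identical p value.
    """
    arrs = _as_groups(groups)
    n = np.array([a.size for a in arrs], dtype=float)
    m = np.array([a.mean() for a in arrs])
    s2 = np.array([a.var(ddof=1) for a in arrs])
    if np.any(s2 == 0):
        bad = int(np.nonzero(s2 == 0)[0][0])
        raise ValueError(
            f"group {bad} has zero variance; Welch's test is undefined "
            "(weights are n/s^2)"
        )
    g = len(arrs)
    w = n / s2
    w_sum = w.sum()
    m_w = (w * m).sum() / w_sum
    a_term = ((1 - w / w_sum) ** 2 / (n - 1)).sum()
    num = (w * (m - m_w) ** 2).sum() / (g - 1)
    den = 1 + 2 * (g - 2) / (g ** 2 - 1) * a_term
    f_stat = num / den
    df1 = g - 1.0
    df2 = (g ** 2 - 1) / (3 * a_term)
    p = float(sps.f.sf(f_stat, df1, df2))
    return TestResult(
        name="welch_anova",
        statistic=float(f_stat),
        df_num=df1,
        df_denom=df2,
        p_value=p,
    )


def adjust_df_half(result: TestResult, halve_num: bool = False) -> TestResult:
    """Recompute the p value with the denominator df halved (floored at 1).

    The statistic is unchanged; only the reference F distribution shrinks.
    Shrinking the denominator df fattens the F tail, so the adjusted p can
    never be smaller than the original.
    """
    df1 = max(result.df_num / 2, 1.0) if halve_num else result.df_num
    df2 = max(result.df_denom / 2, 1.0)
    p_half = float(sps.f.sf(result.statistic, df1, df2))
    return replace(result, p_value_halved_df=p_half)
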