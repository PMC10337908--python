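"""Statistical procedures used across the pipeline.

Hand-rolled only where library coverage is thin: Benjamini-Hochberg
step-up adjustment, Welch's heteroscedastic ANOVA and the Games-Howell
post hoc test are implemented from their published formulas (and
cross-checked against independent implementations in the test suite);
everything routine (Mann-Whitney, one/two-way ANOVA, t tests) dispatches
to scipy/statsmodels.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "welch_anova",
    "games_howell",
    "standard_tests",
    "power_two_groups",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1D array of p values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _as_groups(groups) -> list[np.ndarray]:
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrs:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
        if np.var(g, ddof=1) == 0:
            raise ValueError(
                "zero within-group variance: Welch-type tests are undefined "
                f"(group values all equal {g[0]!r})"
            )
    return arrs


def welch_anova(groups) -> dict:
    """Welch's heteroscedastic one-way ANOVA.

    Groups are weighted by n_i / s_i^2; the F* statistic uses the
    Satterthwaite-type denominator degrees of freedom
    df2 = (k^2 - 1) / (3 * sum((1 - w_i/W)^2 / (n_i - 1))).
    Returns ``{"F": ..., "df1": ..., "df2": ..., "p": ...}``.
    """
    arrs = _as_groups(groups)
    k = len(arrs)
    n = np.array([g.size for g in arrs], dtype=float)
    means = np.array([g.mean() for g in arrs])
    var = np.array([g.var(ddof=1) for g in arrs])
    w = n / var
    big_w = w.sum()
    grand = (w * means).sum() / big_w
    a = (w * (means - grand) ** 2).sum() / (k - 1)
    lam = 3.0 * ((1.0 - w / big_w) ** 2 / (n - 1)).sum() / (k**2 - 1)
    f_star = a / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df1 = k - 1
    df2 = 1.0 / lam
    p = float(sps.f.sf(f_star, df1, df2))
    return {"F": float(f_star), "df1": df1, "df2": float(df2), "p": p}


def games_howell(groups, alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal variances.

    For each pair the standard error is sqrt((s_a^2/n_a + s_b^2/n_b)/2),
    the degrees of freedom are Welch-Satterthwaite, and the statistic
    ``q = |diff| / se`` is referred to the studentized-range distribution
    with k groups.  Confidence intervals use the alpha-level critical q.
    Returns one row per pair: group indices/labels, difference, se, df,
    q, p and the CI bounds.
    """
    labels = list(groups.keys()) if isinstance(groups, Mapping) else None
    arrs = _as_groups(groups)
    k = len(arrs)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = arrs[i], arrs[j]
        na, nb = a.size, b.size
        va, vb = a.var(ddof=1), b.var(ddof=1)
        diff = a.mean() - b.mean()
        se2 = va / na + vb / nb
        se = np.sqrt(se2 / 2.0)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df))
        q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df))
        rows.append(
            {
                "group_a": labels[i] if labels else i,
                "group_b": labels[j] if labels else j,
                "diff": float(diff),
                "se": float(se),
                "df": float(df),
                "q": float(q),
                "p": min(p, 1.0),
                "ci_low": float(diff - q_crit * se),
                "ci_high": float(diff + q_crit * se),
            }
        )
    return pd.DataFrame(rows)


def _two_way_anova(data: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> dict:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "test": "two-way-anova",
        "table": table,
        "p": {
            factor_a: float(table.loc[f"C({factor_a})", "PR(>F)"]),
            factor_b: float(table.loc[f"C({factor_b})", "PR(>F)"]),
            "interaction": float(table.loc[f"C({factor_a}):C({factor_b})", "PR(>F)"]),
        },
        "n": int(len(data)),
    }


def standard_tests(test: str, *args, **kwargs) -> dict:
    """Dispatch to the standard tests used in the analysis.

    ``test`` is one of:

    * ``"mann-whitney"`` -- two samples; two-sided, normal approximation
      with tie correction.
    * ``"anova"`` -- one-way ANOVA over >= 2 samples.
    * ``"pairwise-t-bh"`` -- all pairwise two-sided Welch t tests with
      Benjamini-Hochberg adjustment; pass samples, returns a table.
    * ``"two-way-anova"`` -- pass a DataFrame plus ``value``, ``factor_a``,
      ``factor_b`` column names.

    Results carry the test name, statistic(s), p value(s) and sample size.
    """
    if test == "mann-whitney":
        a, b = (np.asarray(x, dtype=float) for x in args)
        if a.size < 1 or b.size < 1:
            raise ValueError("both samples must be non-empty")
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return {"test": test, "statistic": float(stat), "p": float(p), "n": (a.size, b.size)}
    if test == "anova":
        arrs = [np.asarray(g, dtype=float) for g in args]
        if len(arrs) < 2 or any(g.size < 2 for g in arrs):
            raise ValueError("one-way ANOVA needs >= 2 groups of >= 2 values")
        stat, p = sps.f_oneway(*arrs)
        return {"test": test, "statistic": float(stat), "p": float(p), "n": tuple(g.size for g in arrs)}
    if test == "pairwise-t-bh":
        arrs = [np.asarray(g, dtype=float) for g in args]
        if len(arrs) < 2:
            raise ValueError("need at least 2 groups")
        rows = []
        for i, j in itertools.combinations(range(len(arrs)), 2):
            stat, p = sps.ttest_ind(arrs[i], arrs[j], equal_var=False)
            rows.append({"group_a": i, "group_b": j, "t": float(stat), "p": float(p)})
        table = pd.DataFrame(rows)
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        return {"test": test, "table": table, "n": tuple(g.size for g in arrs)}
    if test == "two-way-anova":
        return _two_way_anova(*args, **kwargs)
    raise ValueError(f"unknown test {test!r}")


def power_two_groups(effect_size: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t test (Cohen's d convention).

    Computed from the noncentral t distribution with noncentrality
    d * sqrt(n/2) and 2n - 2 degrees of freedom.  At zero effect the
    power equals alpha.
    """
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    df = 2 * n_per_group - 2
    nc = effect_size * np.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc)
    return float(power)
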