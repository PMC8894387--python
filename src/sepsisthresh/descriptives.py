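"""Descriptive layer: baseline tables by exposure tertile and the simple
frequentist summaries that accompany them (Wald proportion CIs, 2x2 odds
ratios, Pearson chi-squared tests, one-way ANOVA)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "GroupSummary",
    "proportion_wald_ci",
    "proportion_wilson_ci",
    "odds_ratio_2x2",
    "chi_square_test",
    "one_way_anova",
    "kruskal_wallis",
    "build_baseline_table",
]

# 97.5% normal quantile carried at full precision; rounding happens only in
# rendered tables
Z95 = 1.959963984540054


class TwoByTwo(NamedTuple):
    """Counts (exposed-case, exposed-noncase, unexposed-case, unexposed-noncase)."""

    a: int
    b: int
    c: int
    d: int


def proportion_wald_ci(k: int, n: int, conf: float = 0.95):
    """Normal-approximation (Wald) CI for a binomial proportion, clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p, max(0.0, p - half), min(1.0, p + half)


def proportion_wilson_ci(k: int, n: int, conf: float = 0.95):
    """Wilson score interval (optional alternative to the Wald default)."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return p, max(0.0, centre - half), min(1.0, centre + half)


def odds_ratio_2x2(t: TwoByTwo, conf: float = 0.95):
    """Sample odds ratio ad/(bc) with the Woolf log-scale Wald CI.

    Zero cells are a hard error: a continuity correction changes the estimand
    and is never applied silently here.
    """
    a, b, c, d = t
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        raise ValueError(
            "odds ratio undefined with a zero cell; collapse categories or apply "
            "an explicit continuity correction upstream"
        )
    z = stats.norm.ppf(0.5 + conf / 2.0)
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(np.exp(log_or)), float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def chi_square_test(counts) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table
    (no continuity correction)."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    expected = stats.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise ValueError("zero expected cell count; test undefined")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA F test across k groups of continuous values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: within-group variance is zero, F undefined")
    res = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(g.size for g in groups) - len(groups)
    return float(res.statistic), df1, df2, float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Rank-based alternative to the ANOVA row test (off by default in tables)."""
    res = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupSummary:
    """One baseline-table row: a variable, its per-group summaries, and the
    across-group test."""

    variable: str
    kind: str  # mean_sd | median_iqr | count_pct
    per_group: list[str]
    test: str
    p_value: float


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _fmt_median_iqr(x: pd.Series) -> str:
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def build_baseline_table(
    table: pd.DataFrame,
    groups,
    variables: list[str] | None = None,
    median_iqr_vars: tuple[str, ...] = ("lactate", "sofa"),
    use_rank_tests: bool = False,
) -> list[GroupSummary]:
    """Summarise variables across exposure tertiles with the appropriate test.

    Continuous variables get mean +/- SD (or median (IQR) for the declared
    skewed set) and a one-way ANOVA p-value; categorical/binary variables get
    n (%) per level and a chi-squared p-value.  Missing covariate values are
    excluded from that variable's row (complete-case per row, as baseline
    tables conventionally do).
    """
    labels = groups.labels
    ks = (1, 2, 3)
    if variables is None:
        variables = [c for c in table.columns if c not in ("id",)]
    out: list[GroupSummary] = []
    for var in variables:
        col = table[var]
        if pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 2:
            vals = [col[labels == k].dropna() for k in ks]
            if use_rank_tests:
                _, p = kruskal_wallis(vals)
                test = "kruskal-wallis"
            else:
                _, _, _, p = one_way_anova(vals)
                test = "anova"
            fmt = _fmt_median_iqr if var in median_iqr_vars else _fmt_mean_sd
            out.append(GroupSummary(var, "median_iqr" if var in median_iqr_vars else "mean_sd",
                                    [fmt(v) for v in vals], test, p))
        else:
            levels = sorted(col.dropna().astype(str).unique())
            counts = np.array(
                [[int(((col.astype(str) == lev) & (labels == k)).sum()) for k in ks]
                 for lev in levels]
            )
            _, _, p = chi_square_test(counts)
            cells = []
            for k_idx, k in enumerate(ks):
                n_k = counts[:, k_idx].sum()
                cells.append(
                    "; ".join(
                        f"{lev}: {counts[i, k_idx]} ({100 * counts[i, k_idx] / n_k:.1f}%)"
                        for i, lev in enumerate(levels)
                    )
                )
            out.append(GroupSummary(var, "count_pct", cells, "chi2", p))
    return out


def baseline_table_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Render GroupSummary rows as a DataFrame (tertile columns + p-value)."""
    return pd.DataFrame(
        {
            "variable": [s.variable for s in summaries],
            "tertile_1": [s.per_group[0] for s in summaries],
            "tertile_2": [s.per_group[1] for s in summaries],
            "tertile_3": [s.per_group[2] for s in summaries],
            "test": [s.test for s in summaries],
            "p_value": [s.p_value for s in summaries],
        }
    )
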