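"""Statistical layer: Pearson correlation, Holm–Šidák step-down
adjustment, balanced two-way ANOVA, and paired before/after contrasts.

All p-values are two-tailed.  The Holm–Šidák adjustment follows the
common step-down convention: p-values are sorted ascending,
``adj_(i) = 1 − (1 − p_(i))^(m − i + 1)`` (1-based rank i of m), made
monotone non-decreasing down the sorted list, capped at 1, and returned
in the original input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "pearson",
    "holm_sidak",
    "two_way_anova",
    "paired_before_after",
]


@dataclass(frozen=True)
class StatResult:
    estimate: float
    statistic: float
    df: float
    p: float
    adjusted_p: float | None = None
    flags: tuple[str, ...] = ()


def pearson(x, y) -> StatResult:
    """Pearson product-moment correlation with two-tailed p.

    The p-value comes from t = r·√(n−2)/√(1−r²) on n−2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return StatResult(estimate=r, statistic=np.inf * np.sign(r), df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(estimate=r, statistic=float(t), df=df, p=float(p))


def holm_sidak(pvalues) -> np.ndarray:
    """Step-down Šidák-adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class AnovaResult:
    """Balanced two-way ANOVA table (factors A, B and interaction)."""

    ss: dict = field(default_factory=dict)
    df: dict = field(default_factory=dict)
    f: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = ["A", "B", "A:B", "within"]
        return pd.DataFrame(
            {
                "ss": [self.ss[k] for k in rows],
                "df": [self.df[k] for k in rows],
                "F": [self.f.get(k, np.nan) for k in rows],
                "p": [self.p.get(k, np.nan) for k in rows],
            },
            index=rows,
        )


def two_way_anova(data: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> AnovaResult:
    """Classical balanced two-way ANOVA with interaction.

    Requires a balanced design (every A×B cell has the same number of
    replicates, at least 2).  F = MS_effect / MS_within; p from the F
    distribution.  A fully degenerate input (all values identical)
    reports F = 0 with a ``"degenerate"`` flag.
    """
    df = data[[factor_a, factor_b, value]].dropna()
    a_levels = sorted(df[factor_a].unique())
    b_levels = sorted(df[factor_b].unique())
    I, J = len(a_levels), len(b_levels)
    if I < 2 or J < 2:
        raise ValueError("both factors need at least two levels")
    counts = df.groupby([factor_a, factor_b])[value].count()
    if counts.size != I * J or counts.nunique() != 1:
        raise ValueError("unbalanced design: only the balanced case is supported")
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need at least 2 replicates per cell")

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    cell_mean = df.groupby([factor_a, factor_b])[value].mean()
    a_mean = df.groupby(factor_a)[value].mean()
    b_mean = df.groupby(factor_b)[value].mean()

    ss_a = float(n * J * ((a_mean - grand) ** 2).sum())
    ss_b = float(n * I * ((b_mean - grand) ** 2).sum())
    ss_cells = float(n * ((cell_mean - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((y - grand) ** 2).sum())
    ss_within = ss_total - ss_cells

    dfs = {"A": I - 1, "B": J - 1, "A:B": (I - 1) * (J - 1), "within": I * J * (n - 1)}
    sss = {"A": ss_a, "B": ss_b, "A:B": max(ss_ab, 0.0), "within": max(ss_within, 0.0)}

    flags: tuple[str, ...] = ()
    fvals, pvals = {}, {}
    ms_within = sss["within"] / dfs["within"]
    for eff in ("A", "B", "A:B"):
        if ms_within == 0:
            fvals[eff] = 0.0
            pvals[eff] = np.nan
            flags = ("degenerate",)
        else:
            fv = (sss[eff] / dfs[eff]) / ms_within
            fvals[eff] = float(fv)
            pvals[eff] = float(sps.f.sf(fv, dfs[eff], dfs["within"]))
    return AnovaResult(ss=sss, df=dfs, f=fvals, p=pvals, flags=flags)


def paired_before_after(before, after) -> StatResult:
    """Paired t-test on after − before differences, two-tailed."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be equal-length vectors")
    if before.size < 2:
        raise ValueError("need at least 2 paired subjects")
    d = after - before
    if np.allclose(d, d[0]) and np.std(d) == 0:
        if np.all(d == 0):
            return StatResult(estimate=0.0, statistic=0.0, df=before.size - 1,
                              p=1.0, flags=("degenerate",))
        return StatResult(estimate=float(d.mean()), statistic=np.nan,
                          df=before.size - 1, p=np.nan, flags=("degenerate",))
    t, p = sps.ttest_rel(after, before)
    return StatResult(estimate=float(d.mean()), statistic=float(t),
                      df=before.size - 1, p=float(p))
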