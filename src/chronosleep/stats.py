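"""The study's summary statistics: two-way ANOVA with interaction,
Bonferroni-corrected post-hoc t-tests and Mann-Whitney U tests.

The ANOVA is a fixed-effects full-factorial fit (Type II sums of squares,
which reduce to the classical partition for balanced data); repeated
measurements over time are treated as a between factor, matching the
effect/interaction structure reported in phenotyping figure legends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class AnovaTable:
    """Effects table: one row per effect (A, B, A:B, Residual)."""

    table: pd.DataFrame  # sum_sq, df, F, p
    factor_a: str = "A"
    factor_b: str = "B"

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def two_way_anova(values, factor_a, factor_b, a_name: str = "A", b_name: str = "B") -> AnovaTable:
    """Full-factorial two-way fixed-effects ANOVA with interaction.

    Requires at least two levels per factor and no empty cells.  When the
    data are perfectly constant the F ratios are reported as 0 with p = 1
    (nothing to explain) instead of the indeterminate 0/0.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a, dtype=object),
            "b": np.asarray(factor_b, dtype=object),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    counts = df.groupby(["a", "b"], sort=True).size()
    for la in df["a"].unique():
        for lb in df["b"].unique():
            if (la, lb) not in counts.index:
                raise ValueError(f"empty cell: ({a_name}={la!r}, {b_name}={lb!r})")
    if np.ptp(df["value"].to_numpy()) == 0.0:
        # nothing to explain: all sums of squares are exactly zero
        na, nb = df["a"].nunique(), df["b"].nunique()
        n = len(df)
        rows = {
            a_name: (0.0, float(na - 1), 0.0, 1.0),
            b_name: (0.0, float(nb - 1), 0.0, 1.0),
            f"{a_name}:{b_name}": (0.0, float((na - 1) * (nb - 1)), 0.0, 1.0),
            "Residual": (0.0, float(n - na * nb), np.nan, np.nan),
        }
        table = pd.DataFrame(rows, index=["sum_sq", "df", "F", "p"]).T
        return AnovaTable(table=table, factor_a=a_name, factor_b=b_name)
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    if model.df_resid < 1:
        raise ValueError("residual degrees of freedom < 1; add replicates")
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            "C(a)": a_name,
            "C(b)": b_name,
            "C(a):C(b)": f"{a_name}:{b_name}",
        }
    )
    table = pd.DataFrame(
        {
            "sum_sq": aov["sum_sq"],
            "df": aov["df"],
            "F": aov["F"],
            "p": aov["PR(>F)"],
        }
    )
    resid_ss = table.loc["Residual", "sum_sq"]
    if resid_ss <= 1e-300:
        for name in table.index[:-1]:
            if table.loc[name, "sum_sq"] <= 1e-12:
                table.loc[name, ["F", "p"]] = (0.0, 1.0)
    return AnovaTable(table=table, factor_a=a_name, factor_b=b_name)


def bonferroni_posthoc(
    values, factor_a, factor_b, compare: str = "a", equal_var: bool = False
) -> pd.DataFrame:
    """Per-level two-group t-tests with Bonferroni correction.

    ``compare`` names the two-level factor to test ("a" or "b"); one test
    is run within each level of the other factor, the raw p multiplied by
    the number of levels and capped at 1.  Welch's t is the default
    (percentage data rarely have equal variances); set ``equal_var`` for
    the pooled-variance test.  Levels with fewer than 2 observations per
    group are flagged, not fatal.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a, dtype=object),
            "b": np.asarray(factor_b, dtype=object),
        }
    )
    comp, across = ("a", "b") if compare == "a" else ("b", "a")
    groups = sorted(df[comp].unique())
    if len(groups) != 2:
        raise ValueError(f"factor {compare!r} must have exactly two levels, got {groups}")
    levels = sorted(df[across].unique())
    rows = []
    for level in levels:
        sub = df[df[across] == level]
        x = sub.loc[sub[comp] == groups[0], "value"].to_numpy()
        y = sub.loc[sub[comp] == groups[1], "value"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append(
                {"level": level, "t": np.nan, "p_raw": np.nan, "p_bonf": np.nan, "ok": False}
            )
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sst.ttest_ind(x, y, equal_var=equal_var)
        rows.append({"level": level, "t": float(t), "p_raw": float(p), "p_bonf": np.nan, "ok": True})
    out = pd.DataFrame(rows).set_index("level")
    out["p_bonf"] = np.minimum(out["p_raw"] * len(levels), 1.0)
    return out


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # "exact" or "asymptotic"


@lru_cache(maxsize=64)
def _combination_index(n: int, nx: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), nx)), dtype=np.intp)


_EXACT_LIMIT = 16  # total sample size up to which the permutation null is enumerated


def mann_whitney_u(group_x, group_y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (U reported for ``group_x``).

    For combined sample sizes up to 16 the permutation null is enumerated
    exactly over all C(n, n_x) rank assignments, with midranks handling
    ties; the two-sided p is ``2 * min(P(U <= u), P(U >= u))`` capped at 1.
    Larger samples use the tie-corrected normal approximation.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = sst.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    if n <= _EXACT_LIMIT:
        combos = _combination_index(n, nx)
        u_all = ranks[combos].sum(axis=1) - nx * (nx + 1) / 2.0
        tol = 1e-9
        p_le = np.mean(u_all <= u_obs + tol)
        p_ge = np.mean(u_all >= u_obs - tol)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u=float(u_obs), p=float(p), method="exact")
    res = sst.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")
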