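"""Day-night (ZT16 vs ZT4) differential-expression screen.

Per gene and genotype: a two-sided empirical-Bayes moderated t-test on
log2 values (a plain Welch test is available as a fallback),
Benjamini-Hochberg adjustment across genes, and the study's selection rule
|linear fold-change| > 1.5 AND adjusted p < 0.05.  Fold changes follow the
microarray sign convention: +2^d for day-night log2 difference d >= 0 and
-2^(-d) for d < 0, so a gene halving at ZT16 reports FC = -2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix


@dataclass
class ScreenResult:
    """Per-gene screen table for one genotype.

    Columns: ``log2fc`` (ZT16 - ZT4 group means), ``fold_change`` (signed
    linear scale), ``p_value``, ``p_adjusted``, ``passed``.
    """

    table: pd.DataFrame
    genotype: str
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05

    @property
    def passed_genes(self) -> set:
        return set(self.table.index[self.table["passed"]])


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    lfc = np.asarray(log2fc, dtype=float)
    return np.where(lfc >= 0, 2.0**lfc, -(2.0 ** (-lfc)))


def _welch(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch t p-values; degenerate rows (no variance, equal means)
    get p = 1 rather than an error."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sst.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(diff) < 1e-12)] = 1.0
    p[degenerate & (np.abs(diff) >= 1e-12)] = 0.0
    return p


def _trigamma_inverse(x: float, iterations: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(iterations):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float):
    """Empirical-Bayes scaled-inverse-chi-square prior for gene variances.

    Method-of-moments fit on log sample variances: returns ``(d0, s0_sq)``,
    the prior degrees of freedom (possibly inf when variances look
    homogeneous) and prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - float(digamma(df / 2.0)) + np.log(df / 2.0)
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _moderated(a: np.ndarray, b: np.ndarray):
    """Empirical-Bayes moderated t (pooled variance shrunk across genes).

    Per-gene pooled variances are shrunk toward a prior fitted to all
    genes; the t statistic gains the prior degrees of freedom.  When the
    variances are genuinely homogeneous the fitted prior df grows large
    and the test approaches the known-variance z-test, staying calibrated
    where the small-sample Welch test is conservative.
    """
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    s2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * sst.norm.sf(np.abs(t))
    else:
        p = 2.0 * sst.t.sf(np.abs(t), df_total)
    p[~np.isfinite(t) & (np.abs(diff) < 1e-12)] = 1.0
    p[~np.isfinite(t) & (np.abs(diff) >= 1e-12)] = 0.0
    return np.clip(p, 0.0, 1.0)


def day_night_screen(
    matrix: ExpressionMatrix,
    genotype: str,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    day_timepoint: str = "ZT4",
    night_timepoint: str = "ZT16",
    moderated: bool = True,
) -> ScreenResult:
    """Screen one genotype for day-night differential expression.

    The fold-change cut-off is strict (``|FC| > fc_cutoff``) and applies to
    the linear scale; the p cut-off applies to BH-adjusted p-values.
    ``moderated=False`` falls back to a per-gene Welch test (conservative
    at small replicate numbers).
    """
    night = matrix.samples_for(genotype, night_timepoint)
    day = matrix.samples_for(genotype, day_timepoint)
    if len(night) < 2 or len(day) < 2:
        raise ValueError(
            f"genotype {genotype!r} needs >= 2 replicates per timepoint "
            f"(found {len(day)} at {day_timepoint}, {len(night)} at {night_timepoint})"
        )
    a = matrix.values[night].to_numpy(dtype=float)
    b = matrix.values[day].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p = _moderated(a, b) if moderated else _welch(a, b)
    p_adj = multipletests(p, method="fdr_bh")[1]
    fc = signed_fold_change(log2fc)
    passed = (np.abs(fc) > fc_cutoff) & (p_adj < p_cutoff)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": fc,
            "p_value": p,
            "p_adjusted": p_adj,
            "passed": passed,
        },
        index=matrix.gene_ids,
    )
    return ScreenResult(table=table, genotype=genotype, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff)


@dataclass
class AttenuationResult:
    """Genotype comparison of day-night amplitudes over a shared gene universe."""

    table: pd.DataFrame  # log2fc_wt, log2fc_mut, fc_ratio
    wt_only: set
    shared: set
    mut_only: set


def amplitude_attenuation(result_wt: ScreenResult, result_mut: ScreenResult) -> AttenuationResult:
    """Per-gene ratio of mutant to WT linear fold change, plus pass-set splits.

    The ratio is ``2^(log2fc_mut - log2fc_wt)``; values below 1 mean the
    day-night amplitude is attenuated in the mutant.
    """
    if set(result_wt.table.index) != set(result_mut.table.index):
        raise ValueError("screen results cover different gene universes")
    wt = result_wt.table
    mut = result_mut.table.loc[wt.index]
    ratio = 2.0 ** (mut["log2fc"] - wt["log2fc"])
    table = pd.DataFrame(
        {
            "log2fc_wt": wt["log2fc"],
            "log2fc_mut": mut["log2fc"],
            "fc_ratio": ratio,
        },
        index=wt.index,
    )
    pw, pm = result_wt.passed_genes, result_mut.passed_genes
    return AttenuationResult(
        table=table, wt_only=pw - pm, shared=pw & pm, mut_only=pm - pw
    )
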