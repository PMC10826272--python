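"""Moderated two-group testing with empirical-Bayes variance shrinkage.

The core statistic is the moderated t: a two-group t-test whose per-
analyte variance estimate is shrunk toward a common prior fitted across
all analytes.  Under the hierarchical model

    s_j^2 | sigma_j^2  ~  sigma_j^2 * chi2_d / d
    1 / sigma_j^2      ~  (1 / (d0 * s0^2)) * chi2_d0,

the posterior variance is the precision-weighted blend

    s~_j^2 = (d0 * s0^2 + d * s_j^2) / (d0 + d)

and t_mod,j = (mean_case - mean_control) / (s~_j * sqrt(1/n1 + 1/n2))
follows a t distribution with d0 + d degrees of freedom under the null
(a normal when d0 is infinite).  The prior (d0, s0^2) is estimated by
matching the moments of ln s_j^2, whose distribution under the model is a
shifted log-F; the moment equations involve the digamma and trigamma
functions and are inverted by Newton iteration.

Raw p-values are corrected by the Benjamini-Hochberg step-up rule, and
fold changes are reported on the non-normalized (background-subtracted)
intensity scale where a ratio of group means has its conventional
meaning.  Simple cohort-table statistics (Pearson chi-square, unpaired t)
are provided for baseline-characteristics comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "EBayesParams",
    "estimate_variance_prior",
    "fit_ebayes",
    "moderated_t",
    "bh_adjust",
    "fold_changes",
    "differential_table",
    "chisq_2x2",
    "unpaired_t",
]

CASE, CONTROL = "case", "control"


@dataclass
class EBayesParams:
    """Fitted variance prior and the per-analyte residual variances."""

    d0: float  # prior degrees of freedom; may be math.inf
    s0_sq: float  # prior variance
    s2: pd.Series  # per-analyte residual variance
    df: float  # residual df of each s2 (n1 + n2 - 2)

    def posterior_var(self) -> pd.Series:
        if math.isinf(self.d0):
            return pd.Series(self.s0_sq, index=self.s2.index)
        return (self.d0 * self.s0_sq + self.df * self.s2) / (self.d0 + self.df)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from observed variances.

    Matches mean and variance of e_j = ln s_j^2 - digamma(d/2) + ln(d/2):
    under the model, E[e] = ln s0^2 + digamma(d0/2) - ln(d0/2) and
    Var[e] = trigamma(d/2) + trigamma(d0/2).  When the empirical variance
    of e does not exceed trigamma(d/2) there is no excess dispersion to
    attribute to the prior and d0 is infinite.
    """
    s2 = np.asarray(s2, float)
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero; prior is undefined")
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0.0:
        return math.inf, math.exp(e_mean)
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(e_mean + float(special.digamma(half_d0)) - math.log(half_d0))
    return d0, s0_sq


def _group_arrays(values: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray]:
    g = pd.Series(groups, index=values.index) if not isinstance(groups, pd.Series) else groups
    g = g.reindex(values.index)
    if g.isna().any():
        raise ValueError("every row needs a group label")
    labels = set(g)
    if labels != {CASE, CONTROL}:
        raise ValueError(f"groups must be exactly {{'case', 'control'}}, got {labels}")
    a = values.loc[g == CASE].to_numpy(float)
    b = values.loc[g == CONTROL].to_numpy(float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs n >= 2")
    return a, b


def fit_ebayes(values: pd.DataFrame, groups) -> EBayesParams:
    """Per-analyte pooled residual variances plus the fitted prior.

    ``values`` is wells x analytes on the normalized scale; ``groups``
    labels each well 'case' or 'control'.
    """
    a, b = _group_arrays(values, groups)
    n1, n2 = a.shape[0], b.shape[0]
    df = float(n1 + n2 - 2)
    ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    s2 = ss / df
    d0, s0_sq = estimate_variance_prior(s2, df)
    return EBayesParams(d0=d0, s0_sq=s0_sq, s2=pd.Series(s2, index=values.columns), df=df)


def moderated_t(values: pd.DataFrame, groups, params: EBayesParams) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values per analyte.

    ``params.d0 = 0`` reduces exactly to the classical pooled-variance t;
    ``params.d0 = inf`` shrinks every analyte fully to the prior variance
    and uses the normal reference distribution.
    """
    a, b = _group_arrays(values, groups)
    n1, n2 = a.shape[0], b.shape[0]
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    post_var = params.posterior_var().reindex(values.columns).to_numpy()
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    degenerate = ~(se > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(degenerate, np.nan, mean_diff / np.where(degenerate, 1.0, se))
    if math.isinf(params.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), params.d0 + params.df)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t_mod": t,
            "p_value": p,
            "degenerate": degenerate,
        },
        index=values.columns,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{k >= i} p_(k) * m / k, capped at 1, in the input order.
    NA entries are ignored for the adjustment and propagated.
    """
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    # q_(i) >= p_(i) holds mathematically; enforce it against 1-ulp rounding
    q = np.maximum(q, pv[order])
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def fold_changes(clean: pd.DataFrame, groups) -> pd.DataFrame:
    """Raw-scale fold changes: case mean over control mean per analyte.

    Computed on the background-subtracted, non-normalized matrix.  Both
    group means are floored at eps = 1e-6 of the analyte's value range;
    analytes whose floored means are still non-positive (only possible for
    constant analytes with zero range) get NA with a flag.
    """
    a, b = _group_arrays(clean, groups)
    mc = a.mean(axis=0)
    mx = b.mean(axis=0)
    arr = clean.to_numpy(float)
    eps = 1e-6 * (arr.max(axis=0) - arr.min(axis=0))
    mc_f = np.maximum(mc, eps)
    mx_f = np.maximum(mx, eps)
    bad = (mc_f <= 0) | (mx_f <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(bad, np.nan, mc_f / np.where(bad, 1.0, mx_f))
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {"log2FC": log2fc, "FC": fc, "fc_undefined": bad}, index=clean.columns
    )


def differential_table(
    normalized: pd.DataFrame,
    clean: pd.DataFrame,
    groups,
    analyte_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full differential-reactivity table, sorted by raw p ascending.

    Columns: gene symbols (when metadata is supplied), normalized-scale
    mean difference, moderated t, raw and BH-adjusted p, and raw-scale
    log2FC / FC.
    """
    params = fit_ebayes(normalized, groups)
    tt = moderated_t(normalized, groups, params)
    tt["adj_p_value"] = bh_adjust(tt["p_value"].to_numpy())
    fc = fold_changes(clean[normalized.columns], groups)
    table = tt.join(fc[["log2FC", "FC"]])
    if analyte_meta is not None and "genes" in analyte_meta:
        table.insert(0, "genes", analyte_meta["genes"].reindex(table.index))
    table.index.name = "analyte"
    cols = [c for c in ("genes", "mean_diff", "t_mod", "p_value", "adj_p_value", "log2FC", "FC") if c in table]
    return table[cols].sort_values("p_value", kind="stable")


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def unpaired_t(
    a=None,
    b=None,
    *,
    summary: tuple | None = None,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided unpaired t-test (Welch by default).

    Either raw vectors ``a``/``b`` or ``summary = ((mean1, sd1, n1),
    (mean2, sd2, n2))``.  Degenerate zero-variance input with equal means
    returns (0, 1); with unequal means it is an error (the statistic is
    unbounded).
    """
    if summary is not None:
        (m1, sd1, n1), (m2, sd2, n2) = summary
    else:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        m1, sd1, n1 = a.mean(), a.std(ddof=1), len(a)
        m2, sd2, n2 = b.mean(), b.std(ddof=1), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    stat, p = stats.ttest_ind_from_stats(
        m1, sd1, n1, m2, sd2, n2, equal_var=equal_var
    )
    return float(stat), float(p)
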