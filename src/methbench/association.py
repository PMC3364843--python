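"""Per-CpG supervised association statistics.

Binary phenotypes are tested with the pooled-variance two-sample t; a
continuous phenotype with the slope t of a simple linear regression of
methylation on the phenotype.  For very small samples the ordinary t is
unusable and an empirical-Bayes moderated (regularized) t is provided: the
per-CpG variance s_g^2 is shrunk toward a prior (d0, s0^2) fitted across
features by the method of moments on log s^2,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated statistic gains d0 extra degrees of freedom.  Multiple
testing is summarised by Storey q-values.

All functions return an association table: a DataFrame indexed by CpG with
columns stat, p, q, direction, mean_diff, var, df.  CpGs with zero variance
cannot be ranked; their statistic is NaN and they are excluded from q-value
computation and from prior fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ASSOC_COLUMNS, MethylationMatrix, Phenotype, PriorEstimate

#: df used in place of infinity when the variance prior has no finite df
INF_DF_CAP = 1e6


def _assemble_table(feature_ids, stat, p, mean_diff, var, df) -> pd.DataFrame:
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        # floor protects against p underflowing to exactly 0 on perfect fits
        q[ok] = qvalues(np.maximum(p[ok], 1e-300))
    table = pd.DataFrame(
        {
            "stat": stat,
            "p": p,
            "q": q,
            "direction": np.sign(stat),
            "mean_diff": mean_diff,
            "var": var,
            "df": df,
        },
        index=feature_ids,
    )
    return table[list(ASSOC_COLUMNS)]


def _group_split(matrix: MethylationMatrix, phenotype: Phenotype):
    if phenotype.kind != "binary":
        raise ValueError("binary phenotype required")
    values = matrix.values.loc[:, phenotype.sample_ids].to_numpy()
    y = phenotype.values.to_numpy()
    g0, g1 = values[:, y == 0], values[:, y == 1]
    if g0.shape[1] < 2 or g1.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    return g0, g1


def _pooled_moments(g0, g1):
    n0, n1 = g0.shape[1], g1.shape[1]
    diff = g1.mean(axis=1) - g0.mean(axis=1)
    s2 = ((n0 - 1) * g0.var(axis=1, ddof=1) + (n1 - 1) * g1.var(axis=1, ddof=1)) / (
        n0 + n1 - 2
    )
    se_factor = np.sqrt(1.0 / n0 + 1.0 / n1)
    return diff, s2, se_factor, n0 + n1 - 2


def t_test_by_feature(
    matrix: MethylationMatrix, phenotype: Phenotype, welch: bool = False
) -> pd.DataFrame:
    """Two-sample t per CpG, two-sided p.

    Pooled-variance by default (n0+n1-2 df), which the moderated t nests
    exactly at d0 = 0; ``welch=True`` switches to unequal-variance Welch
    with Satterthwaite df.
    """
    g0, g1 = _group_split(matrix, phenotype)
    if welch:
        n0, n1 = g0.shape[1], g1.shape[1]
        diff = g1.mean(axis=1) - g0.mean(axis=1)
        v0 = g0.var(axis=1, ddof=1) / n0
        v1 = g1.var(axis=1, ddof=1) / n1
        s2 = v0 + v1
        zero_var = s2 <= 1e-20
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(s2)
            df_w = s2**2 / (v0**2 / (n0 - 1) + v1**2 / (n1 - 1))
        t = np.where(zero_var, np.where(np.abs(diff) <= 1e-12, 0.0, np.nan), t)
        df_w = np.where(np.isfinite(df_w), df_w, 1.0)
        p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df_w), np.nan)
        return _assemble_table(matrix.feature_ids, t, p, diff, s2, df_w)
    diff, s2, se_factor, df = _pooled_moments(g0, g1)
    zero_var = s2 <= 1e-20
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (np.sqrt(s2) * se_factor)
    t = np.where(zero_var, np.where(np.abs(diff) <= 1e-12, 0.0, np.nan), t)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    return _assemble_table(matrix.feature_ids, t, p, diff, s2, float(df))


def linear_assoc(matrix: MethylationMatrix, phenotype: Phenotype) -> pd.DataFrame:
    """Simple linear regression of methylation on a continuous phenotype.

    The statistic is the slope t on n-2 df; direction is the slope sign;
    ``var`` holds the residual variance.
    """
    if phenotype.kind != "continuous":
        raise ValueError("continuous phenotype required")
    x = phenotype.values.to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples for regression")
    if np.ptp(x) == 0:
        raise ValueError("phenotype is constant")
    values = matrix.values.loc[:, phenotype.sample_ids].to_numpy()
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = values - values.mean(axis=1, keepdims=True)
    slope = yc @ xc / sxx
    rss = np.maximum((yc * yc).sum(axis=1) - slope**2 * sxx, 0.0)
    df = n - 2
    resid_var = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(resid_var / sxx)
    t = np.where(resid_var == 0, np.where(slope == 0, 0.0, np.sign(slope) * np.inf), t)
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    return _assemble_table(matrix.feature_ids, t, p, slope, resid_var, float(df))


# ---------------------------------------------------------------------------
# Empirical-Bayes variance prior and moderated t
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi'(x) = y for x > 0 by monotone bisection.

    psi' is strictly decreasing from +inf to 0 on (0, inf), so the root is
    unique for any y > 0.
    """
    if y <= 0:
        raise ValueError("trigamma is positive; y must be > 0")
    lo, hi = 1e-12, 1.0
    while special.polygamma(1, hi) > y:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return (lo + hi) / 2.0


def fit_variance_prior(sample_variances, residual_df: float) -> PriorEstimate:
    """Fit a scaled inverse-chi-square prior to per-feature variances.

    Method of moments on z = log(s^2): under the hierarchical model
    s^2 | sigma^2 ~ sigma^2 * chi^2_d / d with sigma^2 ~ d0 s0^2 / chi^2_d0,

        E[z]   = log(s0^2) + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)
        Var[z] = psi'(d/2) + psi'(d0/2).

    d0 is recovered by inverting the trigamma function on
    Var[z] - psi'(d/2); when that difference is <= 0 the spread of the
    variances is entirely sampling noise and d0 = +inf with s0^2 the
    common underlying variance.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances")
    d = float(residual_df)
    z = np.log(s2)
    if np.var(z, ddof=1) < 1e-15:
        # no spread at all: the common value is the prior variance
        return PriorEstimate(np.inf, float(np.exp(z.mean())))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return PriorEstimate(np.inf, float(np.exp(e.mean())))
    half_d0 = trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    log_s0 = float(e.mean()) + special.digamma(half_d0) - np.log(half_d0)
    return PriorEstimate(d0, float(np.exp(log_s0)))


def moderated_t(
    matrix: MethylationMatrix, phenotype: Phenotype, prior: PriorEstimate | None = None
) -> pd.DataFrame:
    """Empirical-Bayes regularized t for a binary phenotype.

    When ``prior`` is None it is fitted from this matrix's pooled
    variances.  d0 = 0 reduces exactly to the ordinary pooled t; d0 = inf
    replaces every per-CpG variance by the prior variance s0^2 (df capped
    for p-value computation).
    """
    g0, g1 = _group_split(matrix, phenotype)
    diff, s2, se_factor, df = _pooled_moments(g0, g1)
    if prior is None:
        prior = fit_variance_prior(s2[s2 > 0], df)
    d0, s0_sq = prior
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        total_df = INF_DF_CAP
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = min(d0 + df, INF_DF_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (np.sqrt(s2_tilde) * se_factor)
    t = np.where(s2_tilde == 0, np.where(diff == 0, 0.0, np.nan), t)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), total_df), np.nan)
    return _assemble_table(matrix.feature_ids, t, p, diff, s2_tilde, float(total_df))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p, lam: float = 0.5) -> float:
    """Fixed-lambda estimate of the null proportion: #{p > lam}/(m(1-lam)),
    capped into (0, 1]."""
    p = np.asarray(p, dtype=float)
    pi0 = np.count_nonzero(p > lam) / (p.size * (1.0 - lam))
    return float(min(max(pi0, 1.0 / p.size), 1.0))


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q(p_(i)) = min_{j>=i} pi0 * m * p_(j) / j, capped at 1.

    With pi0 = 1 this is exactly the Benjamini-Hochberg adjusted p-value.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
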