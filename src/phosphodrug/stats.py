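"""Shared statistical kernel.

Pearson correlation with t-transform p-values, an empirical-Bayes
moderated t-test with moment-matched hyperparameters, one-sided
hypergeometric set enrichment, Benjamini-Hochberg adjustment and the RV
matrix-correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special as spc
from scipy import stats as sps

from .datatypes import DataError


@dataclass
class TestResult:
    """Result of a single hypothesis test.

    ``effect`` is context dependent (correlation r, mean difference, ...).
    ``q`` is filled in by callers after Benjamini-Hochberg adjustment over
    the relevant family. ``undefined`` flags degenerate inputs (constant
    series, zero matrices) instead of raising.
    """

    statistic: float
    p: float
    effect: float
    n: int
    q: float = float("nan")
    undefined: bool = False


def pearson_test(x, y) -> TestResult:
    """Two-sided Pearson correlation test via the t transform with n-2 df.

    Constant input series yield an UNDEFINED-flagged result, not an
    exception.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise DataError(f"length mismatch: {xv.shape} vs {yv.shape}")
    n = xv.size
    if n < 3:
        raise DataError(f"pearson_test requires >= 3 pairs, got {n}")
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise DataError("pearson_test requires complete pairs; filter first")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        return TestResult(np.nan, np.nan, np.nan, n, undefined=True)
    r = float((xc * yc).sum() / (sx * sy))
    r = min(1.0, max(-1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(p), r, n)


def moderated_t(
    group_a,
    group_b,
    prior_df: float = 0.0,
    prior_var: float = 0.0,
) -> TestResult:
    """Moderated two-sample t-test with a shrunken pooled variance.

    The posterior variance is s~^2 = (d0*s0^2 + d*s^2) / (d0 + d) with
    d = nA + nB - 2 residual degrees of freedom; the statistic is
    (meanA - meanB) / (s~ * sqrt(1/nA + 1/nB)) and p comes from a t
    distribution with d0 + d df. prior_df = 0 recovers the classical
    pooled t-test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DataError(f"moderated_t requires >= 2 observed values per group, got ({na}, {nb})")
    if prior_df < 0 or prior_var < 0:
        raise DataError("prior_df and prior_var must be non-negative")
    d = na + nb - 2
    s2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    s2 /= d
    if np.isinf(prior_df):
        s2_post, df_post = prior_var, np.inf
    else:
        s2_post = (prior_df * prior_var + d * s2) / (prior_df + d)
        df_post = prior_df + d
    effect = float(a.mean() - b.mean())
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    if se == 0.0:
        if effect == 0.0:
            return TestResult(0.0, 1.0, 0.0, na + nb, undefined=True)
        return TestResult(np.inf if effect > 0 else -np.inf, 0.0, effect, na + nb)
    stat = effect / se
    if np.isinf(df_post):
        p = 2.0 * sps.norm.sf(abs(stat))
    else:
        p = 2.0 * sps.t.sf(abs(stat), df_post)
    return TestResult(float(stat), float(p), effect, na + nb)


def estimate_variance_prior(variances, df: int) -> tuple[float, float]:
    """Moment-match (prior_df, prior_var) from per-feature sample variances.

    Under the scaled inverse-chi-square model, log s^2 has
    var(log s2) = trigamma(d/2) + trigamma(d0/2) and
    E[log s2] = log s0^2 + digamma(d/2) - digamma(d0/2) - log(d/d0).
    We solve the trigamma equation for d0 by bisection. This is a
    deterministic stand-in for a full empirical-Bayes ML fit; at
    desk scale the difference is immaterial.
    """
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 3:
        return 0.0, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(s2)
    target = z.var(ddof=1) - spc.polygamma(1, df / 2.0)
    if target <= 1e-8:
        # observed variances more concentrated than chi2 sampling noise:
        # effectively infinite prior df; cap for numeric stability
        d0 = 1e6
    else:
        lo, hi = 1e-3, 1e6
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if spc.polygamma(1, mid / 2.0) > target:
                lo = mid
            else:
                hi = mid
        d0 = 0.5 * (lo + hi)
    log_s0 = z.mean() - spc.digamma(df / 2.0) + spc.digamma(d0 / 2.0) + np.log(df / d0)
    return float(d0), float(np.exp(log_s0))


def moderated_t_matrix(
    matrix: pd.DataFrame,
    labels: pd.Series,
) -> pd.DataFrame:
    """Row-wise moderated t-tests (label 1 vs label 0) over a feature matrix.

    Hyperparameters (prior_df, prior_var) are estimated by moment
    matching of the observed per-row variance distribution. Rows with
    fewer than 2 observed values in either group get NaN statistics.
    Returns a DataFrame with columns statistic, p, q, effect, n.
    """
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise DataError("phenotype labels missing for some cell lines")
    pos = matrix.loc[:, labels == 1]
    neg = matrix.loc[:, labels == 0]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise DataError("both phenotype classes need >= 2 cell lines")

    na = pos.notna().sum(axis=1)
    nb = neg.notna().sum(axis=1)
    ok = (na >= 2) & (nb >= 2)
    d_row = (na + nb - 2).astype(float)
    ssa = ((pos.sub(pos.mean(axis=1), axis=0)) ** 2).sum(axis=1, skipna=True)
    ssb = ((neg.sub(neg.mean(axis=1), axis=0)) ** 2).sum(axis=1, skipna=True)
    s2 = (ssa + ssb) / d_row.where(d_row > 0)

    # prior estimated at the modal residual df (desk-scale matrices are
    # near-balanced; per-row df refinements change little)
    df_mode = int(d_row[ok].mode().iloc[0]) if ok.any() else 2
    d0, s0 = estimate_variance_prior(s2[ok & (d_row == df_mode)].to_numpy(), df_mode)

    s2_post = (d0 * s0 + d_row * s2) / (d0 + d_row)
    effect = pos.mean(axis=1) - neg.mean(axis=1)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    stat = effect / se
    p = pd.Series(
        2.0 * sps.t.sf(np.abs(stat.to_numpy()), d0 + d_row.to_numpy()),
        index=matrix.index,
    )
    stat[~ok] = np.nan
    p[~ok] = np.nan
    out = pd.DataFrame(
        {"statistic": stat, "p": p, "effect": effect, "n": (na + nb).astype(int)}
    )
    out["q"] = np.nan
    out.loc[p.notna(), "q"] = bh_adjust(p[p.notna()].to_numpy())
    return out


def hypergeom_enrich(
    overlap: int,
    set_size: int,
    group_size: int,
    universe: int,
) -> TestResult:
    """One-sided enrichment p-value: P(X >= overlap) for hypergeometric X.

    Equivalent to the one-sided Fisher exact test on the 2x2 enrichment
    table.
    """
    if not (0 <= overlap <= min(set_size, group_size) <= universe):
        raise DataError(
            "inconsistent counts: need 0 <= overlap <= min(set_size, group_size)"
            f" <= universe, got overlap={overlap}, set={set_size},"
            f" group={group_size}, universe={universe}"
        )
    if set_size > universe or group_size > universe:
        raise DataError("set or group larger than the universe")
    p = float(sps.hypergeom.sf(overlap - 1, universe, set_size, group_size))
    p = min(1.0, max(0.0, p))
    expected = set_size * group_size / universe if universe else np.nan
    effect = overlap / expected if expected else np.nan
    return TestResult(float(overlap), p, float(effect), group_size)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, order preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rv_coefficient(x, y) -> TestResult:
    """RV coefficient between two matrices sharing rows (cell lines).

    RV = tr(XX'YY') / sqrt(tr((XX')^2) tr((YY')^2)) after internal column
    centering. A zero matrix yields an UNDEFINED-flagged result.
    """
    X = np.asarray(x, dtype=float)
    Y = np.asarray(y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise DataError(f"row count mismatch: {X.shape} vs {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sx = Xc @ Xc.T
    Sy = Yc @ Yc.T
    denom = np.sqrt((Sx * Sx).sum() * (Sy * Sy).sum())
    if denom == 0.0:
        return TestResult(np.nan, np.nan, np.nan, X.shape[0], undefined=True)
    rv = float((Sx * Sy).sum() / denom)
    return TestResult(rv, np.nan, rv, X.shape[0])


def results_to_frame(results: dict[str, TestResult]) -> pd.DataFrame:
    """Serialize TestResults to the (id, statistic, effect, n, p, q) layout."""
    return pd.DataFrame(
        {
            "id": list(results),
            "statistic": [r.statistic for r in results.values()],
            "effect": [r.effect for r in results.values()],
            "n": [r.n for r in results.values()],
            "p": [r.p for r in results.values()],
            "q": [r.q for r in results.values()],
        }
    )
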