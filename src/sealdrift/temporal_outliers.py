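"""Temporal allele-frequency outlier scan against a drift null.

Each locus gets an ordinary least-squares regression of cohort allele
frequency on calendar year.  Loci simulated under the neutral
Wright-Fisher/logistic null define an envelope -- the maximum absolute slope
over all simulated loci -- and an observed locus is called an outlier when
its regression is individually significant (p < alpha) AND its absolute
slope exceeds that envelope.  The scan also compares the observed and
simulated slope distributions as a whole: a variance-ratio F test (excess
dispersion of observed rates of change) and a pooled two-sample t test of
the mean rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .wf_logistic_sim import CohortFrequencySeries

__all__ = [
    "LocusTrend", "OutlierReport", "locus_trend", "locus_trends",
    "slope_envelope", "call_outliers", "compare_slope_distributions",
]


@dataclass(frozen=True)
class LocusTrend:
    """OLS regression of one locus' allele frequency on calendar year."""

    locus_id: str
    slope: float
    intercept: float
    p_value: float          # NaN when degenerate
    r_squared: float
    n_points: int
    degenerate: bool = False


def locus_trends(series: CohortFrequencySeries,
                 weighted: bool = False) -> pd.DataFrame:
    """Vectorized per-locus OLS of frequency on year.

    Returns a DataFrame indexed by locus_id with columns slope, intercept,
    p_value, r_squared, n_points, degenerate.  The slope p-value is the
    two-sided t test with n-2 df; zero residual variance is flagged
    degenerate (perfect non-constant fit or constant series) with p = NaN.
    With ``weighted=True`` points are weighted by their gene-copy counts.
    """
    x = series.years
    Y = series.freq
    if x.size < 2:
        raise ValueError("need at least 2 time points")
    w = np.asarray(series.n_genes, float) if weighted else np.ones_like(x)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (Y * w).sum(axis=1) / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = ((Y - ybar[:, None]) * (w * (x - xbar))).sum(axis=1)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = Y - (intercept[:, None] + np.outer(slope, x))
    sse = (w * resid ** 2).sum(axis=1)
    syy = (w * (Y - ybar[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, 1.0 - sse / syy, 0.0)
    n = x.size
    degen = np.isclose(sse, 0.0, atol=1e-18)
    p = np.full(Y.shape[0], np.nan)
    if n > 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(sse / (n - 2) / sxx)
            t = slope / se
        ok = ~degen
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 2)
    return pd.DataFrame({
        "slope": slope, "intercept": intercept, "p_value": p,
        "r_squared": np.clip(r2, 0.0, 1.0), "n_points": n,
        "degenerate": degen,
    }, index=pd.Index(series.locus_ids, name="locus_id"))


def locus_trend(years: np.ndarray, freqs: np.ndarray,
                locus_id: str = "locus") -> LocusTrend:
    """Single-locus convenience wrapper around :func:`locus_trends`."""
    years = np.asarray(years, float)
    freqs = np.asarray(freqs, float)
    if np.unique(years).size < 2:
        raise ValueError("need >= 2 distinct years")
    series = CohortFrequencySeries(
        locus_ids=np.array([locus_id]), years=years,
        freq=freqs[None, :], n_genes=np.zeros(years.size, dtype=int))
    row = locus_trends(series).iloc[0]
    return LocusTrend(locus_id=locus_id, slope=float(row.slope),
                      intercept=float(row.intercept),
                      p_value=float(row.p_value),
                      r_squared=float(row.r_squared),
                      n_points=int(row.n_points),
                      degenerate=bool(row.degenerate))


def slope_envelope(sim_trends: pd.DataFrame,
                   significant_only: bool = False,
                   alpha: float = 0.05) -> float:
    """Maximum absolute slope over simulated loci.

    Degenerate regressions are excluded.  ``significant_only`` restricts the
    envelope to simulated loci with p < alpha (sensitivity-analysis variant;
    the default uses ALL simulated loci).
    """
    t = sim_trends.loc[~sim_trends["degenerate"].astype(bool)]
    if significant_only:
        t = t.loc[t["p_value"] < alpha]
    if len(t) == 0:
        raise ValueError("no usable simulated trends for the envelope")
    return float(np.abs(t["slope"]).max())


@dataclass
class OutlierReport:
    """Outcome of a temporal outlier scan."""

    envelope: float
    alpha: float
    outlier_ids: tuple[str, ...]
    obs_trends: pd.DataFrame
    sim_trends: pd.DataFrame | None = None
    variance_F: float | None = None
    variance_F_df: tuple[int, int] | None = None
    variance_F_p: float | None = None
    mean_t: float | None = None
    mean_t_p: float | None = None
    n_degenerate_excluded: int = 0

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_ids)


def call_outliers(obs_trends: pd.DataFrame, envelope: float,
                  alpha: float = 0.05) -> OutlierReport:
    """Apply the outlier rule: p < alpha AND |slope| > envelope."""
    if envelope < 0:
        raise ValueError("envelope must be >= 0")
    p = obs_trends["p_value"].to_numpy()
    s = np.abs(obs_trends["slope"].to_numpy())
    with np.errstate(invalid="ignore"):
        hit = (p < alpha) & (s > envelope)
    hit &= ~obs_trends["degenerate"].to_numpy(bool)
    ids = tuple(obs_trends.index[hit])
    return OutlierReport(envelope=envelope, alpha=alpha, outlier_ids=ids,
                         obs_trends=obs_trends,
                         n_degenerate_excluded=int(
                             obs_trends["degenerate"].sum()))


def compare_slope_distributions(obs_trends: pd.DataFrame,
                                sim_trends: pd.DataFrame):
    """Variance-ratio F and pooled two-sample t between slope sets.

    F = var(observed slopes) / var(simulated slopes) with
    (n_obs - 1, n_sim - 1) df and a two-sided p-value; degenerate
    regressions are excluded from both sets.  Returns
    ``(F, (df1, df2), p_F, t, p_t)``; F statistics are NaN-flagged when the
    simulated variance is zero.
    """
    a = obs_trends.loc[~obs_trends["degenerate"].astype(bool), "slope"].to_numpy()
    b = sim_trends.loc[~sim_trends["degenerate"].astype(bool), "slope"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 non-degenerate slopes per set")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = (a.size - 1, b.size - 1)
    if vb == 0:
        F, pF = np.nan, np.nan
    else:
        F = va / vb
        cdf = stats.f.cdf(F, *df)
        pF = float(2 * min(cdf, 1 - cdf))
    t, pt = stats.ttest_ind(a, b, equal_var=True)
    return float(F), df, pF, float(t), float(pt)
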