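"""Linear trend with AR(1) errors, and 2x2 association statistics.

The trend model for a quarterly rate series is

    Y(t) = A + B*t + a(t),        a(t) = k*a(t-1) + e(t),  e(t) ~ N(0, s2)

with |k| < 1 (stationary errors).  ``Ar1Trend`` estimates A, B, k under
the exact Gaussian likelihood: for fixed k the series is whitened with
the stationary AR(1) transform (Prais-Winsten rows), A and B drop out by
ordinary least squares on the whitened data, and the resulting profile
criterion is maximized over k by bounded scalar search.  By default the
criterion is the *restricted* likelihood (REML), which corrects the
well-known downward small-sample bias of the ML autocorrelation estimate
and brings the trend test close to its nominal size at quarterly series
lengths; plain maximum likelihood and conditional least squares are
available as options.  The trend test is a Wald t-test of B = 0 on n - 3
degrees of freedom (three parameters besides the innovation variance).

Also provided: sample autocorrelations with the +/-2/sqrt(n) band used to
judge stationarity, the Woolf (log) confidence interval for an odds
ratio, and the Pearson chi-square test for a 2x2 table.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = ["Ar1Trend", "Ar1TrendResults", "fit_ar1_trend", "acf",
           "TwoByTwo", "odds_ratio_woolf", "chi_square_2x2", "anova_oneway"]

_K_BOUND = 0.999


def _whiten(y: np.ndarray, X: np.ndarray, k: float):
    """Stationary AR(1) whitening of response and design."""
    n = len(y)
    w = np.empty_like(y)
    Xw = np.empty_like(X)
    c = np.sqrt(1.0 - k * k)
    w[0] = c * y[0]
    Xw[0] = c * X[0]
    w[1:] = y[1:] - k * y[:-1]
    Xw[1:] = X[1:] - k * X[:-1]
    return w, Xw


def _profile(y: np.ndarray, X: np.ndarray, k: float, method: str):
    """Profile out (A, B, s2) at fixed k; returns (criterion, beta, rss, Xw)."""
    n = len(y)
    if method == "cls":  # conditional least squares: drop the first observation
        w = y[1:] - k * y[:-1]
        Xw = X[1:] - k * X[:-1]
        n = len(w)
    else:
        w, Xw = _whiten(y, X, k)
    beta, *_ = np.linalg.lstsq(Xw, w, rcond=None)
    resid = w - Xw @ beta
    rss = float(resid @ resid)
    if method == "reml":
        p = X.shape[1]
        s2 = max(rss / (n - p), 1e-300)
        _, logdet = np.linalg.slogdet(Xw.T @ Xw)
        ll = (-0.5 * (n - p) * (np.log(2 * np.pi * s2) + 1.0)
              + 0.5 * np.log(1.0 - k * k) - 0.5 * logdet)
    else:
        s2 = max(rss / n, 1e-300)
        ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
        if method == "mle":
            ll += 0.5 * np.log(1.0 - k * k)
    return ll, beta, rss, Xw


@dataclass
class Ar1TrendResults:
    """Fitted linear-trend-with-AR(1)-errors model.

    Attributes mirror the model symbols: ``A`` (intercept), ``B`` (slope
    per quarter), ``k`` (error autocorrelation), with standard errors,
    the Wald p-value for no trend, series length and log-likelihood.
    """

    A: float
    B: float
    k: float
    se_A: float
    se_B: float
    sigma2: float
    p_trend: float
    n: int
    loglik: float
    df_resid: int
    method: str
    converged: bool

    @property
    def tvalue_B(self) -> float:
        return self.B / self.se_B

    def conf_int_B(self, alpha: float = 0.05) -> tuple[float, float]:
        half = stats.t.ppf(1 - alpha / 2, self.df_resid) * self.se_B
        return self.B - half, self.B + half

    def summary(self) -> str:
        lo, hi = self.conf_int_B()
        lines = [
            "Linear trend with AR(1) errors",
            "=" * 46,
            f"n quarters        {self.n:>10d}",
            f"method            {self.method:>10s}",
            f"log-likelihood    {self.loglik:>10.3f}",
            "-" * 46,
            f"A  (intercept)    {self.A:>10.4f}  se {self.se_A:.4f}",
            f"B  (slope/quarter){self.B:>10.4f}  se {self.se_B:.4f}",
            f"   95% CI for B   [{lo:.4f}, {hi:.4f}]",
            f"k  (autocorr)     {self.k:>10.4f}",
            f"p (H0: B = 0)     {self.p_trend:>10.4g}  (t, df={self.df_resid})",
            "=" * 46,
        ]
        return "\n".join(lines)


class Ar1Trend:
    """Model object for a quarterly rate series with a linear time trend.

    Parameters
    ----------
    series : array-like
        Rate values by quarter; NaN entries (undefined rates from empty
        denominators) are dropped, with their count kept on the model.
    t : array-like, optional
        Time index; defaults to 1..n over the non-missing values.
    """

    def __init__(self, series, t=None):
        y = np.asarray(series, dtype=float)
        if t is None:
            t = np.arange(1, len(y) + 1, dtype=float)
        else:
            t = np.asarray(t, dtype=float)
        keep = np.isfinite(y)
        self.n_dropped = int((~keep).sum())
        self.y = y[keep]
        self.t = t[keep]
        if len(self.y) < 8:
            raise ValueError("series too short: need >= 8 finite quarters")
        self.X = np.column_stack([np.ones_like(self.t), self.t])

    def fit(self, method: str = "reml", k_fixed: float | None = None) -> Ar1TrendResults:
        """Fit by restricted ML (default), exact ML (``'mle'``) or
        conditional least squares (``'cls'``).

        ``k_fixed`` pins the autocorrelation (0 reduces the fit to OLS).
        """
        if method not in ("reml", "mle", "cls"):
            raise ValueError(f"unknown method: {method!r}")
        if k_fixed is not None:
            if not abs(k_fixed) < 1:
                raise ValueError("|k| must be < 1")
            k_hat, converged = float(k_fixed), True
        else:
            res = optimize.minimize_scalar(
                lambda k: -_profile(self.y, self.X, k, method)[0],
                bounds=(-_K_BOUND, _K_BOUND), method="bounded",
                options={"xatol": 1e-8})
            if not res.success:
                raise RuntimeError(f"AR(1) optimizer failed: {res.message}")
            k_hat, converged = float(res.x), bool(res.success)
        ll, beta, rss, Xw = _profile(self.y, self.X, k_hat, method)
        n = len(self.y)
        df = n - 3 if k_fixed is None else n - 2
        s2_unbiased = rss / max(df, 1)
        cov = s2_unbiased * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.diag(cov))
        tstat = beta[1] / se[1]
        p = 2 * stats.t.sf(abs(tstat), df)
        return Ar1TrendResults(
            A=float(beta[0]), B=float(beta[1]), k=k_hat,
            se_A=float(se[0]), se_B=float(se[1]), sigma2=rss / n,
            p_trend=float(p), n=n, loglik=float(ll), df_resid=df,
            method=method, converged=converged)


def fit_ar1_trend(series, t=None, method: str = "reml") -> Ar1TrendResults:
    """Convenience wrapper: ``Ar1Trend(series, t).fit(method)``."""
    return Ar1Trend(series, t).fit(method=method)


def acf(series, max_lag: int) -> dict:
    """Sample autocorrelations with the 2-standard-error band.

    Returns lags 1..max_lag, the band half-width 2/sqrt(n), and which lags
    fall outside it (the nonstationarity screen applied to each series
    before trend modelling).
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < max_lag + 2:
        raise ValueError("series too short for requested max_lag")
    if np.allclose(y, y[0]):
        raise ValueError("constant series: autocorrelation undefined")
    r = _sm_acf(y, nlags=max_lag, fft=False)[1:]
    band = 2.0 / np.sqrt(n)
    lags = np.arange(1, max_lag + 1)
    return {"lags": lags, "acf": r, "band": band,
            "outside": lags[np.abs(r) > band]}


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome counts: a, b = exposed with/without the event;
    c, d = unexposed with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def odds_ratio_woolf(table: TwoByTwo, correction: bool = False,
                     alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Odds ratio ad/bc with the Woolf log-normal confidence interval.

    Zero cells raise unless ``correction`` adds Haldane-Anscombe +0.5 to
    every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        raise ValueError("zero cell: use correction=True for Haldane-Anscombe")
    orx = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(orx) - z * se), np.exp(np.log(orx) + z * se)
    return float(orx), (float(lo), float(hi))


def chi_square_2x2(table: TwoByTwo) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        raise ValueError("zero margin: chi-square undefined")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(stat, 1))
    return float(stat), 1, p


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F and p (thin wrapper for group-mean comparisons)."""
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
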