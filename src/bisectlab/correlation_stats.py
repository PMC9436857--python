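"""Rank-based correlation inference for the bisection/EBR analyses.

Spearman correlations with asymptotic-t p-values, bias-corrected and
accelerated (BCa) bootstrap confidence intervals, a robust bivariate
outlier rule, partial and semi-partial rank correlations, a dependent-
correlation comparison with a bootstrap difference CI, the paired t-test
with d_z effect size, and the exact a-priori sample-size computation for
a correlation test.

Two-tailed p-values are used throughout; directional hypotheses are
handled by the Bayes-factor module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import integrate, special, stats
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class CorrResult:
    rho: float
    n: int
    p_value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    outlier_mask: Optional[np.ndarray] = None
    method: str = "spearman"


@dataclass
class CorrDiff:
    """Difference between two correlations sharing one variable.

    ``t_stat``/``d_z`` come from the jackknife pseudo-value distribution
    of the difference with df = n - 3; this construction is a
    reconstruction of common reporting practice, flagged in ``method``.
    """

    rho_a: float
    rho_b: float
    z_diff: float
    diff: float
    diff_ci_low: float
    diff_ci_high: float
    significant: bool
    t_stat: float
    df: int
    d_z: float
    n: int
    method: str = "bootstrap-diff-ci; t/d_z reconstructed from jackknife pseudo-values"


@dataclass
class PairedTestResult:
    t_stat: float
    df: int
    p_value: float
    d_z: float
    n: int


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    # sums of (half-integer) ranks are exact in double precision, so
    # perfectly monotone data give exactly +/-1
    rx, ry = rankdata(x), rankdata(y)
    n = len(rx)
    sxx = n * np.sum(rx * rx) - np.sum(rx) ** 2
    syy = n * np.sum(ry * ry) - np.sum(ry) ** 2
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in ranks; Spearman rho undefined")
    rho = (n * np.sum(rx * ry) - np.sum(rx) * np.sum(ry)) / np.sqrt(sxx * syy)
    return float(np.clip(rho, -1.0, 1.0))


def spearman_p_value(rho: float, n: int) -> float:
    """Two-tailed p from t = rho sqrt((n-2)/(1-rho^2)) on n-2 df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman(x, y) -> CorrResult:
    """Spearman rank correlation (average ranks for ties) with asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 4:
        raise ValueError("need n >= 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    rho = _spearman_rho(x, y)
    return CorrResult(rho=rho, n=len(x), p_value=spearman_p_value(rho, len(x)))


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def _spearman_rows(xm: np.ndarray, ym: np.ndarray) -> np.ndarray:
    """Row-wise Spearman for (B, n) matrices (vectorized bootstrap path)."""
    rx = rankdata(xm, axis=1)
    ry = rankdata(ym, axis=1)
    n = rx.shape[1]
    sx, sy = rx.sum(axis=1), ry.sum(axis=1)
    sxx = n * (rx * rx).sum(axis=1) - sx**2
    syy = n * (ry * ry).sum(axis=1) - sy**2
    num = n * (rx * ry).sum(axis=1) - sx * sy
    den = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.clip(np.where(den > 0, num / den, np.nan), -1.0, 1.0)


def bca_ci(
    x,
    y,
    statistic: Optional[Callable] = None,
    n_boot: int = 10000,
    level: float = 0.95,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """BCa bootstrap CI for a paired statistic (default: Spearman rho).

    Pairs are resampled with replacement; the bias correction z0 comes
    from the proportion of bootstrap statistics below the point
    estimate, the acceleration from jackknife skewness, and the
    percentile endpoints are adjusted accordingly.  A degenerate
    bootstrap distribution (all replicates equal) returns a point-mass
    interval with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need n >= 8 for a stable acceleration estimate")
    rng = rng if rng is not None else np.random.default_rng(seed)

    fast = statistic is None
    stat = _spearman_rho if fast else statistic
    theta_hat = float(stat(x, y))

    idx = rng.integers(0, n, size=(n_boot, n))
    if fast:
        boots = _spearman_rows(x[idx], y[idx])
        boots = boots[np.isfinite(boots)]
    else:
        boots = []
        for row in idx:
            try:
                boots.append(float(stat(x[row], y[row])))
            except ValueError:
                continue
        boots = np.asarray(boots)
    if boots.size == 0:
        raise RuntimeError("all bootstrap replicates failed")
    if np.ptp(boots) == 0:
        warnings.warn("degenerate bootstrap distribution; returning point interval", RuntimeWarning)
        return float(boots[0]), float(boots[0])

    prop = np.clip(np.mean(boots < theta_hat), 0.5 / boots.size, 1 - 0.5 / boots.size)
    z0 = stats.norm.ppf(prop)

    # jackknife acceleration
    if fast:
        mask = ~np.eye(n, dtype=bool)
        xj = np.broadcast_to(x, (n, n))[mask].reshape(n, n - 1)
        yj = np.broadcast_to(y, (n, n))[mask].reshape(n, n - 1)
        jack = _spearman_rows(xj, yj)
    else:
        jack = np.array([stat(np.delete(x, i), np.delete(y, i)) for i in range(n)])
    d = jack.mean() - jack
    s2 = np.sum(d**2)
    a = 0.0 if s2 == 0 else np.sum(d**3) / (6.0 * s2**1.5)

    alpha = (1.0 - level) / 2.0
    z = stats.norm.ppf([alpha, 1.0 - alpha])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    lo, hi = np.quantile(boots, adj)
    return float(lo), float(hi)


def spearman_with_ci(x, y, n_boot: int = 10000, level: float = 0.95, seed=None, rng=None) -> CorrResult:
    res = spearman(x, y)
    res.ci_low, res.ci_high = bca_ci(x, y, n_boot=n_boot, level=level, seed=seed, rng=rng)
    return res


# ---------------------------------------------------------------------------
# bivariate outliers
# ---------------------------------------------------------------------------

def remove_bivariate_outliers(x, y) -> np.ndarray:
    """Flag bivariate outliers (True = outlier) with a projection boxplot rule.

    Both variables are centered on their medians and scaled by the
    normalized MAD; the 1.5-IQR boxplot rule is then applied to the two
    orthogonal diagonal projections of the standardized cloud, which are
    the principal axes of an elliptical bivariate scatter.  A point
    flagged on either projection is an outlier.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need n >= 10 for outlier detection")

    def robust_z(v):
        med = np.median(v)
        mad = stats.median_abs_deviation(v, scale="normal")
        if mad == 0:
            iqr = np.subtract(*np.percentile(v, [75, 25]))
            if iqr == 0:
                raise ValueError("zero spread; outlier rule undefined")
            mad = iqr / 1.349
        return (v - med) / mad

    xs, ys = robust_z(x), robust_z(y)
    mask = np.zeros(n, dtype=bool)
    for proj in ((xs + ys) / np.sqrt(2.0), (xs - ys) / np.sqrt(2.0)):
        q1, q3 = np.percentile(proj, [25, 75])
        iqr = q3 - q1
        mask |= (proj < q1 - 1.5 * iqr) | (proj > q3 + 1.5 * iqr)
    if mask.mean() > 0.25:
        warnings.warn(f"{mask.sum()}/{n} points flagged as outliers (> 25%)", RuntimeWarning)
    return mask


# ---------------------------------------------------------------------------
# partial / semi-partial Spearman
# ---------------------------------------------------------------------------

def partial_spearman(x, y, z, semi_on: Optional[str] = None) -> CorrResult:
    """Partial (or semi-partial) Spearman correlation of x and y given z.

    All variables are rank-transformed; the partial is computed from the
    rank (Pearson) correlations.  ``semi_on='y'`` removes z only from y
    (``r_x(y.z)``), ``semi_on='x'`` only from x; ``None`` gives the full
    partial.  p-value from t on n - 3 df.
    """
    if semi_on not in (None, "x", "y"):
        raise ValueError("semi_on must be None, 'x' or 'y'")
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must be equal length")
    n = len(x)
    r_xy = _spearman_rho(x, y)
    r_xz = _spearman_rho(x, z)
    r_yz = _spearman_rho(y, z)
    if min(1 - r_xz**2, 1 - r_yz**2) <= 1e-12:
        raise ValueError("control variable collinear with x or y; partial undefined")
    num = r_xy - r_xz * r_yz
    if semi_on is None:
        r = num / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        method = "partial-spearman"
    elif semi_on == "y":
        r = num / np.sqrt(1 - r_yz**2)
        method = "semipartial-spearman (z removed from y)"
    else:
        r = num / np.sqrt(1 - r_xz**2)
        method = "semipartial-spearman (z removed from x)"
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrResult(rho=float(r), n=n, p_value=p, method=method)


# ---------------------------------------------------------------------------
# dependent correlations and paired t
# ---------------------------------------------------------------------------

def compare_dependent_correlations(
    x, y_a, y_b, n_boot: int = 10000, seed=None, rng: Optional[np.random.Generator] = None
) -> CorrDiff:
    """Compare rho(x, y_a) vs rho(x, y_b) on the same participants.

    The difference CI is a percentile bootstrap over participants
    resampled jointly; significance means the CI excludes 0.  The Fisher
    z-difference is reported alongside.  t and d_z summarize the
    jackknife pseudo-value distribution of the difference (df = n - 3).
    """
    x, y_a, y_b = (np.asarray(v, dtype=float) for v in (x, y_a, y_b))
    n = len(x)
    if n < 10:
        raise ValueError("need overlap n >= 10")
    rng = rng if rng is not None else np.random.default_rng(seed)

    rho_a = _spearman_rho(x, y_a)
    rho_b = _spearman_rho(x, y_b)
    diff = rho_a - rho_b
    z_diff = float(np.arctanh(np.clip(rho_a, -1 + 1e-12, 1 - 1e-12))
                   - np.arctanh(np.clip(rho_b, -1 + 1e-12, 1 - 1e-12)))

    idx = rng.integers(0, n, size=(n_boot, n))
    d_boot = _spearman_rows(x[idx], y_a[idx]) - _spearman_rows(x[idx], y_b[idx])
    d_boot = d_boot[np.isfinite(d_boot)]
    lo, hi = np.quantile(d_boot, [0.025, 0.975])

    # jackknife pseudo-values of the difference
    mask = ~np.eye(n, dtype=bool)
    xj = np.broadcast_to(x, (n, n))[mask].reshape(n, n - 1)
    aj = np.broadcast_to(y_a, (n, n))[mask].reshape(n, n - 1)
    bj = np.broadcast_to(y_b, (n, n))[mask].reshape(n, n - 1)
    d_loo = _spearman_rows(xj, aj) - _spearman_rows(xj, bj)
    pseudo = n * diff - (n - 1) * d_loo
    df = n - 3
    sd = pseudo.std(ddof=1)
    t = float(pseudo.mean() / sd * np.sqrt(df)) if sd > 0 else 0.0
    return CorrDiff(
        rho_a=float(rho_a), rho_b=float(rho_b), z_diff=z_diff, diff=float(diff),
        diff_ci_low=float(lo), diff_ci_high=float(hi),
        significant=not (lo <= 0.0 <= hi),
        t_stat=t, df=df, d_z=float(t / np.sqrt(df)), n=n,
    )


def paired_ttest(a, b) -> PairedTestResult:
    """Paired t-test on the differences with effect size d_z = t / sqrt(n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need paired vectors with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return PairedTestResult(t_stat=0.0, df=len(a) - 1, p_value=1.0, d_z=0.0, n=len(a))
        raise ValueError("zero-variance nonzero differences; t undefined")
    res = stats.ttest_rel(a, b)
    n = len(a)
    t = float(res.statistic)
    return PairedTestResult(t_stat=t, df=n - 1, p_value=float(res.pvalue), d_z=t / np.sqrt(n), n=n)


# ---------------------------------------------------------------------------
# exact sampling distribution of r, power and sample size
# ---------------------------------------------------------------------------

def log_pdf_sample_r(r, rho: float, n: int):
    """Log of the exact density of the sample correlation under bivariate
    normality with population correlation ``rho`` and sample size ``n``
    (Hotelling's form with a Gauss hypergeometric factor)."""
    r = np.asarray(r, dtype=float)
    lg = special.gammaln
    h = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    return (
        np.log(n - 2.0) + lg(n - 1.0) - 0.5 * np.log(2.0 * np.pi) - lg(n - 0.5)
        + (n - 1.0) / 2.0 * np.log1p(-rho**2)
        + (n - 4.0) / 2.0 * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(h)
    )


def pdf_sample_r(r, rho: float, n: int):
    return np.exp(log_pdf_sample_r(r, rho, n))


def correlation_power_exact(n: int, rho_alt: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of the correlation test of rho = 0 at sample size n.

    The critical value comes from the null exact distribution (via the t
    transform); power integrates the exact alternative density over the
    rejection region by adaptive quadrature.
    """
    if n < 4:
        return 0.0
    a = alpha / 2.0 if tails == 2 else alpha
    tc = stats.t.ppf(1.0 - a, n - 2)
    rc = tc / np.sqrt(tc**2 + (n - 2))
    hi, _ = integrate.quad(lambda r: pdf_sample_r(r, rho_alt, n), rc, 1.0)
    if tails == 2:
        lo, _ = integrate.quad(lambda r: pdf_sample_r(r, rho_alt, n), -1.0, -rc)
        return float(lo + hi)
    return float(hi) if rho_alt >= 0 else float(1.0 - hi)


def required_n_exact(
    rho_alt: float, alpha: float = 0.05, power: float = 0.80, tails: int = 2, n_max: int = 10000
) -> int:
    """Smallest n at which the exact correlation test reaches the target power."""
    if not 0.0 < abs(rho_alt) < 1.0:
        raise ValueError("rho_alt must be in (0, 1) in magnitude")
    for n in range(4, n_max + 1):
        if correlation_power_exact(n, rho_alt, alpha, tails) >= power:
            return n
    raise ValueError(f"target power not attainable with n <= {n_max}")
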