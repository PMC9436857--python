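"""Maximum-likelihood logistic psychometric fitting for bisection tasks.

The observer model is a two-parameter logistic psychometric function

    psi(x; alpha, beta) = 1 / (1 + exp(-beta * (x - alpha)))

with guess and lapse rates fixed at 0.  ``alpha`` is the bisection point
(BP): the stimulus level judged equidistant from the two trained anchors.
``beta`` is the slope (1 / stimulus units).  From a fitted function we
derive

* the difference limen ``DL = (x(0.75) - x(0.25)) / 2 = ln(3) / beta``,
  half the distance between the 75% and 25% points, and
* the Weber fraction ``WF = DL / BP``, a dimensionless precision index
  (lower WF = finer discrimination).

Fitting maximizes the product-binomial likelihood of per-level response
counts.  Goodness of fit is assessed with a deviance p-value (``pDev``):
a parametric bootstrap in which datasets simulated from the fitted
function are refitted and the observed deviance is compared against the
simulated deviance distribution.  Participants whose fits give
``pDev < .05`` are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

LN3 = float(np.log(3.0))

#: slope bounds (per stimulus unit); an MLE pinned at a bound is treated
#: as non-converged (data carry no finite-slope information).
BETA_MIN = 1e-5
BETA_MAX = 1e3

#: multi-start grid resolution for the MLE search.
N_ALPHA_STARTS = 11
N_BETA_STARTS = 15

_P_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ResponseSummary:
    """Per-level response counts for one participant and task.

    ``n_long_or_red`` counts the responses matching the upper anchor
    ("long" in the temporal task, "red" in the color task).  Fractional
    counts are allowed so that expected-proportion data can be fitted in
    self-consistency checks.
    """

    levels: np.ndarray
    n_trials: np.ndarray
    n_long_or_red: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=float)
        self.n_long_or_red = np.asarray(self.n_long_or_red, dtype=float)
        if not (self.levels.shape == self.n_trials.shape == self.n_long_or_red.shape):
            raise ValueError("levels, n_trials and n_long_or_red must be aligned")
        if np.any(self.n_long_or_red < -1e-9) or np.any(self.n_long_or_red > self.n_trials + 1e-9):
            raise ValueError("counts must satisfy 0 <= n_long_or_red <= n_trials")
        if int(np.sum(self.n_trials > 0)) < 2:
            raise ValueError("need at least 2 levels with trials")

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_trials > 0, self.n_long_or_red / self.n_trials, np.nan)

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        *,
        include_reminders: bool = False,
        include_training: bool = False,
    ) -> "ResponseSummary":
        """Aggregate a trial table (one participant, one task) to counts.

        Test-phase trials always count; reminder and training trials are
        excluded unless requested.
        """
        phases = {"test"}
        if include_reminders:
            phases.add("reminder")
        if include_training:
            phases.add("training")
        sub = trials[trials["phase"].isin(phases)]
        if sub.empty:
            raise ValueError("no trials left after phase filtering")
        pos = sub["response"].isin(("long", "red"))
        grp = sub.assign(_pos=pos.astype(float)).groupby("stimulus", sort=True)
        levels = np.array(sorted(grp.groups))
        n = grp.size().reindex(levels).to_numpy(dtype=float)
        k = grp["_pos"].sum().reindex(levels).to_numpy(dtype=float)
        return cls(levels=levels, n_trials=n, n_long_or_red=k)


@dataclass
class PsychFit:
    """A fitted logistic psychometric function and its derived indices."""

    alpha: float
    beta: float
    loglik: float
    deviance: float
    converged: bool
    guess_rate: float = 0.0
    lapse_rate: float = 0.0
    pdev: Optional[float] = None
    n_trials_total: float = 0.0

    @property
    def bp(self) -> float:
        return self.alpha

    @property
    def dl(self) -> float:
        return LN3 / self.beta

    @property
    def wf(self) -> float:
        if self.alpha <= 0:
            raise ValueError("Weber fraction undefined for alpha <= 0")
        return self.dl / self.alpha


# ---------------------------------------------------------------------------
# psychometric function and likelihood
# ---------------------------------------------------------------------------

def psi_logistic(x, alpha: float, beta: float):
    """Logistic psychometric function ``1 / (1 + exp(-beta (x - alpha)))``.

    Strictly increasing in ``x``; ``psi(alpha) = 0.5`` and
    ``psi(alpha ± ln(3)/beta) = 0.75 / 0.25``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return expit(beta * (np.asarray(x, dtype=float) - alpha))


def _binom_loglik(p: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """Binomial log-likelihood kernel (binomial coefficients omitted)."""
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def saturated_loglik(summary: ResponseSummary) -> float:
    """Log-likelihood of the saturated model (observed proportions, 0·log0 = 0)."""
    n, k = summary.n_trials, summary.n_long_or_red
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, k / n, 0.0)
        t1 = np.where(k > 0, k * np.log(np.where(k > 0, p, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(np.where(n - k > 0, 1.0 - p, 1.0)), 0.0)
    return float(np.sum(t1 + t2))


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

def _start_grid(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    span = float(levels.max() - levels.min())
    alphas = np.linspace(levels.min(), levels.max(), N_ALPHA_STARTS)
    # betas span difference limens from 5x the level range down to range/200
    betas = np.geomspace(LN3 / (5.0 * span), 200.0 * LN3 / span, N_BETA_STARTS)
    return alphas, betas


def fit_pf_mle(summary: ResponseSummary, *, loglik_tol: float = 1e-8) -> PsychFit:
    """Fit (alpha, beta) by maximum likelihood with guess = lapse = 0.

    A multi-start grid over alpha (level range) x beta (log-spaced) seeds
    a Nelder-Mead refinement on (alpha, log beta).  The slope is bounded
    in ``[BETA_MIN, BETA_MAX]``; an estimate pinned at a bound — e.g. for
    perfectly separable step data — is reported with ``converged=False``
    and the caller decides exclusion.

    Returns
    -------
    PsychFit
        With ``loglik`` (kernel), ``deviance = 2 (LL_sat - LL_model)``
        and the convergence flag.
    """
    levels = summary.levels
    n, k = summary.n_trials, summary.n_long_or_red
    span = float(levels.max() - levels.min())

    props = summary.proportions
    seen = ~np.isnan(props)
    identifiable = np.nanstd(props[seen]) > 0
    # perfectly separable data (every observed proportion 0 or 1) push the
    # slope to +inf; the finite point the optimizer stops at is arbitrary
    separable = identifiable and bool(
        np.all((props[seen] <= _P_EPS) | (props[seen] >= 1 - _P_EPS))
    )

    lo_a, hi_a = levels.min() - 2 * span, levels.max() + 2 * span
    lo_lb, hi_lb = np.log(BETA_MIN), np.log(BETA_MAX)

    def nll(theta: np.ndarray) -> float:
        a, lb = theta
        pen = 0.0
        if a < lo_a:
            pen += 1e4 * (lo_a - a) ** 2 / span**2
            a = lo_a
        elif a > hi_a:
            pen += 1e4 * (a - hi_a) ** 2 / span**2
            a = hi_a
        if lb < lo_lb:
            pen += 1e4 * (lo_lb - lb) ** 2
            lb = lo_lb
        elif lb > hi_lb:
            pen += 1e4 * (lb - hi_lb) ** 2
            lb = hi_lb
        p = expit(np.exp(lb) * (levels - a))
        return -_binom_loglik(p, n, k) + pen

    # vectorized grid evaluation
    alphas, betas = _start_grid(levels)
    aa, bb = np.meshgrid(alphas, betas, indexing="ij")
    p_grid = expit(bb[..., None] * (levels[None, None, :] - aa[..., None]))
    p_grid = np.clip(p_grid, _P_EPS, 1 - _P_EPS)
    ll_grid = np.sum(k * np.log(p_grid) + (n - k) * np.log1p(-p_grid), axis=-1)
    i, j = np.unravel_index(np.argmax(ll_grid), ll_grid.shape)
    x0 = np.array([aa[i, j], np.log(bb[i, j])])

    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": loglik_tol, "maxiter": 2000},
    )
    alpha_hat = float(res.x[0])
    beta_hat = float(np.clip(np.exp(res.x[1]), BETA_MIN, BETA_MAX))
    ll = _binom_loglik(psi_logistic(levels, alpha_hat, beta_hat), n, k)
    dev = 2.0 * (saturated_loglik(summary) - ll)

    at_bound = beta_hat <= BETA_MIN * 1.0001 or beta_hat >= BETA_MAX * 0.9999
    converged = bool(res.success) and identifiable and not at_bound and not separable
    return PsychFit(
        alpha=alpha_hat, beta=beta_hat, loglik=ll, deviance=max(dev, 0.0),
        converged=converged, n_trials_total=float(n.sum()),
    )


def derive_bp_dl_wf(fit: PsychFit) -> tuple[float, float, float]:
    """Return (BP, DL, WF) from a converged fit.

    BP = alpha; DL = ln(3)/beta (half the 25%–75% spread); WF = DL/BP.
    Raises for alpha <= 0 (WF undefined on a non-positive bisection point).
    """
    if not fit.converged:
        raise ValueError("derive_bp_dl_wf requires a converged fit")
    return fit.bp, fit.dl, fit.wf


# ---------------------------------------------------------------------------
# vectorized Newton (IRLS) batch fitter
# ---------------------------------------------------------------------------

def _fit_logistic_batch(
    levels: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    max_iter: int = 80,
    tol: float = 1e-10,
) -> dict:
    """ML-fit many response tables at once by Newton/IRLS.

    The logistic psychometric model is a logistic regression
    ``eta = b0 + b1 x`` with ``alpha = -b0/b1`` and ``beta = b1``; Newton
    iterations on (b0, b1) converge quadratically.  ``k`` has shape
    (B, L); ``levels`` and ``n`` shape (L,).  Fits with non-positive or
    out-of-bound slope, or no likelihood improvement, are flagged
    non-converged.  Same likelihood as :func:`fit_pf_mle`; used where
    thousands of refits are needed (deviance bootstraps, large cohorts).
    """
    levels = np.asarray(levels, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.atleast_2d(np.asarray(k, dtype=float))
    B, L = k.shape

    # weighted-least-squares start on continuity-corrected empirical logits
    p0 = (k + 0.5) / (n + 1.0)
    y = np.log(p0 / (1 - p0))
    w = n * p0 * (1 - p0)
    sw = w.sum(axis=1)
    mx = (w * levels).sum(axis=1) / sw
    my = (w * y).sum(axis=1) / sw
    sxx = (w * (levels - mx[:, None]) ** 2).sum(axis=1)
    sxy = (w * (levels - mx[:, None]) * (y - my[:, None])).sum(axis=1)
    b1 = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), 1.0)
    span = float(levels.max() - levels.min())
    b1 = np.clip(b1, 1e-6 / span, None)  # start on the increasing branch
    b0 = my - b1 * mx

    def loglik(b0, b1):
        p = expit(np.clip(b0[:, None] + b1[:, None] * levels, -35, 35))
        p = np.clip(p, _P_EPS, 1 - _P_EPS)
        return (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=1)

    ll = loglik(b0, b1)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(b0[:, None] + b1[:, None] * levels, -35, 35)
        p = expit(eta)
        W = n * p * (1 - p)
        r = k - n * p
        g0 = r.sum(axis=1)
        g1 = (r * levels).sum(axis=1)
        h00 = W.sum(axis=1)
        h01 = (W * levels).sum(axis=1)
        h11 = (W * levels**2).sum(axis=1)
        det = np.maximum(h00 * h11 - h01**2, 1e-300)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = np.where(active, 1.0, 0.0)
        nb0, nb1 = b0 + step * d0, b1 + step * d1
        nll_ = loglik(nb0, nb1)
        worse = active & (nll_ < ll - 1e-12)
        for _h in range(25):  # step-halving where the full step overshoots
            if not worse.any():
                break
            step = np.where(worse, step * 0.5, step)
            nb0 = b0 + step * d0
            nb1 = b1 + step * d1
            nll_ = np.where(worse, loglik(nb0, nb1), nll_)
            worse = active & (nll_ < ll - 1e-12)
        improved = nll_ - ll
        b0, b1, ll = nb0, nb1, nll_
        active = active & (improved > tol)

    beta = b1
    alpha = np.where(np.abs(beta) > 1e-300, -b0 / np.where(beta != 0, beta, 1.0), np.nan)
    ok = (beta > BETA_MIN) & (beta < BETA_MAX) & np.isfinite(alpha) & ~active
    # saturated LL per row
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(n > 0, k / n, 0.0)
        t1 = np.where(k > 0, k * np.log(np.where(k > 0, ps, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(np.where(n - k > 0, 1 - ps, 1.0)), 0.0)
    ll_sat = (t1 + t2).sum(axis=1)
    dev = np.maximum(2.0 * (ll_sat - ll), 0.0)
    return {"alpha": alpha, "beta": beta, "loglik": ll, "deviance": dev, "converged": ok}


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def goodness_of_fit_pdev(
    fit: PsychFit,
    summary: ResponseSummary,
    n_sim: int = 1000,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Deviance p-value by parametric bootstrap of the fitted function.

    ``n_sim`` datasets are simulated from the fitted psychometric
    function at the observed per-level trial counts, each is refitted,
    and ``pDev`` is the proportion of simulated deviances at least as
    large as the observed deviance (ties count as extreme).  Simulations
    whose refit fails are excluded from the proportion, with a warning
    when more than 5% fail.  Reproducible given ``seed``.
    """
    if not fit.converged:
        raise ValueError("goodness_of_fit_pdev requires a converged fit")
    rng = rng if rng is not None else np.random.default_rng(seed)
    levels, n = summary.levels, summary.n_trials
    p_hat = np.asarray(psi_logistic(levels, fit.alpha, fit.beta))
    n_int = np.round(n).astype(int)
    k_sim = rng.binomial(n_int[None, :], p_hat[None, :], size=(n_sim, len(levels)))
    out = _fit_logistic_batch(levels, n_int.astype(float), k_sim.astype(float))
    ok = out["converged"]
    # rescue rare failures with the robust single-fit path
    for idx in np.flatnonzero(~ok):
        try:
            f = fit_pf_mle(ResponseSummary(levels, n_int.astype(float), k_sim[idx].astype(float)))
        except ValueError:
            continue
        if f.converged:
            out["deviance"][idx] = f.deviance
            ok[idx] = True
    n_ok = int(ok.sum())
    if n_ok < n_sim * 0.95:
        warnings.warn(
            f"{n_sim - n_ok}/{n_sim} bootstrap refits failed; pDev based on {n_ok} simulations",
            RuntimeWarning,
        )
    if n_ok == 0:
        raise RuntimeError("all bootstrap refits failed")
    return float(np.mean(out["deviance"][ok] >= fit.deviance - 1e-9))


# ---------------------------------------------------------------------------
# cohort-level exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    fits: pd.DataFrame,
    ebr: Optional[pd.DataFrame] = None,
    pdev_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop poorly fitted and EBR-missing participants, task-wise.

    Parameters
    ----------
    fits : DataFrame
        Columns ``participant_id, task, pdev, converged`` (plus any fit
        columns); one row per participant x task.
    ebr : DataFrame, optional
        Columns ``participant_id, ebr``; a missing row or NaN marks a
        participant without a usable recording.  Such participants stay
        fitted but are excluded from correlational analyses.

    Returns
    -------
    (retained, log) : retained rows of ``fits`` (with an ``has_ebr``
    column when ``ebr`` is given) and an exclusion log with columns
    ``participant_id, task, reason``.
    """
    fits = fits.reset_index(drop=True)
    log_rows = []
    keep = pd.Series(True, index=fits.index)
    for idx, row in fits.iterrows():
        if not bool(row.get("converged", True)):
            keep[idx] = False
            log_rows.append((row["participant_id"], row["task"], "fit_not_converged"))
        elif pd.notna(row.get("pdev")) and row["pdev"] < pdev_threshold:
            keep[idx] = False
            log_rows.append((row["participant_id"], row["task"], f"pdev<{pdev_threshold}"))
    retained = fits[keep].copy()
    if ebr is not None:
        ebr_ok = ebr.dropna(subset=["ebr"]).set_index("participant_id")["ebr"]
        retained["has_ebr"] = retained["participant_id"].isin(ebr_ok.index)
        for pid in sorted(set(fits["participant_id"]) - set(ebr_ok.index)):
            log_rows.append((pid, "*", "missing_ebr"))
    log = pd.DataFrame(log_rows, columns=["participant_id", "task", "reason"])
    return retained, log
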