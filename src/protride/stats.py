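"""Residual statistics and outlier calling.

Residuals between observed and model-expected log intensities are converted to
two-sided tail probabilities under either a per-protein Gaussian or a
Student's-t distribution whose degrees of freedom are shared across proteins
(two-pass fit: per-protein maximum likelihood for all three parameters, then a
refit of location and scale with the degrees of freedom pinned to the median
of the first pass).  Tail probabilities are adjusted sample-wise with the
Benjamini-Yekutieli (default) or Benjamini-Hochberg step-up procedure; these
are model diagnostics ranked like, but not interpretable as, p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "ResidualSet",
    "TDistFit",
    "TwoPassStudentT",
    "compute_residuals",
    "gaussian_tail_probs",
    "fit_t_two_pass",
    "t_tail_probs",
    "adjust_tail_probs",
    "adjust_tail_probs_samplewise",
    "call_outliers",
    "assemble_results",
]

_P_FLOOR = 1e-300  # avoid log-domain underflow in reports
_NU_BOUNDS = (0.5, 1000.0)


@dataclass
class ResidualSet:
    """Residuals e = x - x_hat with per-protein observed-cell summaries."""

    e: np.ndarray  # (n_samples, n_proteins), NaN where missing
    mean_j: np.ndarray
    sd_j: np.ndarray  # unbiased, observed cells only


def compute_residuals(X: np.ndarray, X_hat: np.ndarray, M: np.ndarray) -> ResidualSet:
    e = np.where(M > 0, X - X_hat, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_j = np.nanmean(e, axis=0)
        sd_j = np.nanstd(e, axis=0, ddof=1)
    return ResidualSet(e=e, mean_j=mean_j, sd_j=sd_j)


def gaussian_tail_probs(res: ResidualSet) -> np.ndarray:
    """Two-sided Gaussian tail probabilities of standardized residuals."""
    bad = ~(res.sd_j > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} protein(s) with zero residual sd; tail probabilities omitted",
            UserWarning,
        )
    sd = np.where(bad, np.nan, res.sd_j)
    z = (res.e - res.mean_j) / sd
    p = 2.0 * sps.norm.sf(np.abs(z))
    return np.clip(p, _P_FLOOR, 1.0)


@dataclass
class TDistFit:
    """Per-protein Student's-t location/scale with shared degrees of freedom."""

    nu0: float
    mu_j: np.ndarray
    tau_j: np.ndarray
    first_pass_nu: np.ndarray


def _t_nll(theta, x):
    mu, log_tau, log_nu = theta
    return -np.sum(sps.t.logpdf(x, df=np.exp(log_nu), loc=mu, scale=np.exp(log_tau)))


def _t_nll_grad(theta, x):
    """Negative log-likelihood and its gradient in (mu, log tau, log nu)."""
    from scipy.special import digamma

    mu, log_tau, log_nu = theta
    tau, nu = np.exp(log_tau), np.exp(log_nu)
    u = (x - mu) / tau
    u2 = u**2
    nll = -np.sum(sps.t.logpdf(x, df=nu, loc=mu, scale=tau))
    g_mu = -np.sum((nu + 1.0) * u / (tau * (nu + u2)))
    g_ltau = -np.sum((nu + 1.0) * u2 / (nu + u2) - 1.0)
    dl_dnu = (
        0.5 * digamma((nu + 1.0) / 2.0)
        - 0.5 * digamma(nu / 2.0)
        - 0.5 / nu
        - 0.5 * np.log1p(u2 / nu)
        + (nu + 1.0) * u2 / (2.0 * nu * (nu + u2))
    )
    g_lnu = -nu * np.sum(dl_dnu)
    return nll, np.array([g_mu, g_ltau, g_lnu])


def _fit_t_single(x: np.ndarray) -> tuple[float, float, float]:
    """3-parameter Student's-t MLE for one protein's residuals.

    Initialized at median / 1.48*MAD / nu=10; degrees of freedom bounded to
    [0.5, 1000].  Falls back to moment estimates if optimization fails twice.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale0 = max(1.4826 * mad, 1e-8)
    log_nu_bounds = (np.log(_NU_BOUNDS[0]), np.log(_NU_BOUNDS[1]))
    bounds = [(None, None), (np.log(1e-10), None), (log_nu_bounds[0], log_nu_bounds[1])]

    for start in (
        (med, np.log(scale0), np.log(10.0)),
        (float(np.mean(x)), np.log(max(np.std(x), 1e-8)), np.log(10.0)),
    ):
        opt = optimize.minimize(
            _t_nll_grad, start, args=(x,), jac=True, method="L-BFGS-B", bounds=bounds
        )
        if opt.success and np.isfinite(opt.fun):
            mu, log_tau, log_nu = opt.x
            return float(mu), float(np.exp(log_tau)), float(np.exp(log_nu))
    warnings.warn("t MLE failed for a protein; falling back to moment estimates", UserWarning)
    return float(np.mean(x)), float(max(np.std(x, ddof=1), 1e-8)), 10.0


def _em_location_scale(e: np.ndarray, nu: float, max_iter: int = 200, tol: float = 1e-10):
    """Vectorized EM for per-protein t location/scale at fixed degrees of freedom.

    Operates column-wise on a residual matrix with NaN at missing cells; EM
    for the t distribution with known df is monotone in the likelihood.
    """
    obs = ~np.isnan(e)
    n_j = obs.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmedian(e, axis=0)
        mad = np.nanmedian(np.abs(e - mu), axis=0)
    tau = np.maximum(1.4826 * mad, 1e-8)
    ez = np.where(obs, e, 0.0)
    for _ in range(max_iter):
        d2 = np.where(obs, ((ez - mu) / tau) ** 2, 0.0)
        w = np.where(obs, (nu + 1.0) / (nu + d2), 0.0)
        mu_new = (w * ez).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-12)
        tau2_new = (w * (ez - mu_new) ** 2).sum(axis=0) / np.maximum(n_j, 1)
        tau_new = np.sqrt(np.maximum(tau2_new, 1e-16))
        if np.max(np.abs(mu_new - mu)) < tol and np.max(np.abs(tau_new - tau)) < tol:
            mu, tau = mu_new, tau_new
            break
        mu, tau = mu_new, tau_new
    return mu, tau


def fit_t_two_pass(res: ResidualSet, M: np.ndarray | None = None, min_obs: int = 10) -> TDistFit:
    """Two-pass Student's-t fit with a shared degrees-of-freedom parameter.

    Pass 1 estimates (location, scale, df) per protein by maximum likelihood;
    the shared df is the median of the per-protein estimates.  Pass 2 refits
    location and scale per protein with the df fixed at that value.
    """
    e = res.e
    obs = ~np.isnan(e)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs < min_obs):
        j = int(np.argmax(n_obs < min_obs))
        raise ValueError(
            f"protein at column {j} has only {int(n_obs[j])} observed residuals (< {min_obs})"
        )
    first_pass_nu = np.empty(e.shape[1])
    for j in range(e.shape[1]):
        _, _, nu = _fit_t_single(e[obs[:, j], j])
        first_pass_nu[j] = nu
    nu0 = float(np.median(first_pass_nu))
    mu_j, tau_j = _em_location_scale(e, nu0)
    return TDistFit(nu0=nu0, mu_j=mu_j, tau_j=tau_j, first_pass_nu=first_pass_nu)


def t_tail_probs(res: ResidualSet, tfit: TDistFit) -> np.ndarray:
    """Two-sided Student's-t tail probabilities with the shared df."""
    bad = ~(tfit.tau_j > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} protein(s) with zero t scale; tail probabilities omitted",
            UserWarning,
        )
    tau = np.where(bad, np.nan, tfit.tau_j)
    z = (res.e - tfit.mu_j) / tau
    p = 2.0 * sps.t.sf(np.abs(z), df=tfit.nu0)
    return np.clip(p, _P_FLOOR, 1.0)


class TwoPassStudentT(BaseEstimator):
    """Estimator wrapper around the two-pass shared-df Student's-t fit.

    Attributes after ``fit``: ``nu0_``, ``mu_``, ``tau_``, ``first_pass_nu_``.
    """

    def __init__(self, min_obs: int = 10):
        self.min_obs = min_obs

    def fit(self, residuals: np.ndarray, mask: np.ndarray | None = None):
        e = np.asarray(residuals, dtype=float)
        if mask is not None:
            e = np.where(np.asarray(mask) > 0, e, np.nan)
        res = ResidualSet(
            e=e,
            mean_j=np.nanmean(e, axis=0),
            sd_j=np.nanstd(e, axis=0, ddof=1),
        )
        tfit = fit_t_two_pass(res, min_obs=self.min_obs)
        self.nu0_ = tfit.nu0
        self.mu_ = tfit.mu_j
        self.tau_ = tfit.tau_j
        self.first_pass_nu_ = tfit.first_pass_nu
        self._fit = tfit
        return self

    def tail_probs(self, residuals: np.ndarray) -> np.ndarray:
        e = np.asarray(residuals, dtype=float)
        res = ResidualSet(e=e, mean_j=self.mu_, sd_j=self.tau_)
        return t_tail_probs(res, self._fit)


def adjust_tail_probs(p: np.ndarray, method: str = "by") -> np.ndarray:
    """Step-up adjustment of one sample's tail probabilities (BY or BH)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    method = method.lower()
    if method not in ("by", "bh"):
        raise ValueError("method must be 'by' or 'bh'")
    return np.minimum(sps.false_discovery_control(p, method=method), 1.0)


def adjust_tail_probs_samplewise(
    P: np.ndarray, M: np.ndarray, method: str = "by"
) -> np.ndarray:
    """Adjust a tail-probability matrix per sample over its observed proteins."""
    out = np.full_like(P, np.nan, dtype=float)
    for i in range(P.shape[0]):
        sel = (M[i] > 0) & ~np.isnan(P[i])
        out[i, sel] = adjust_tail_probs(P[i, sel], method=method)
    return out


def call_outliers(adjusted: np.ndarray, cutoff: float = 0.1) -> np.ndarray:
    """Binary outlier flags: adjusted tail probability at or below the cutoff."""
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(adjusted), 0, (adjusted <= cutoff).astype(int))


def assemble_results(
    X: np.ndarray,
    X_hat: np.ndarray,
    M: np.ndarray,
    res: ResidualSet,
    tail_probs: np.ndarray,
    adjusted: np.ndarray,
    cutoff: float = 0.1,
    sample_ids=None,
    protein_ids=None,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """One row per observed (sample, protein) cell, sorted within sample by
    adjusted tail probability.  Fold changes are on the raw intensity scale."""
    n, p = X.shape
    if not (X_hat.shape == M.shape == tail_probs.shape == (n, p)):
        raise ValueError("component shapes are misaligned")
    sample_ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids)
    protein_ids = np.arange(p) if protein_ids is None else np.asarray(protein_ids)
    ii, jj = np.nonzero(M > 0)
    lfc = X[ii, jj] - X_hat[ii, jj]
    with np.errstate(invalid="ignore", divide="ignore"):
        zscores = (res.e[ii, jj] - res.mean_j[jj]) / res.sd_j[jj]
    df = pd.DataFrame(
        {
            "sample_id": sample_ids[ii],
            "protein_id": protein_ids[jj],
            "observed": X[ii, jj],
            "expected": X_hat[ii, jj],
            "log2_fc": lfc,
            "fold_change": np.power(log_base, lfc),
            "zscore": zscores,
            "tail_prob": tail_probs[ii, jj],
            "adj_tail_prob": adjusted[ii, jj],
        }
    )
    df["is_outlier"] = call_outliers(df["adj_tail_prob"].to_numpy(), cutoff)
    order = np.lexsort((df["adj_tail_prob"].to_numpy(), ii))
    return df.iloc[order].reset_index(drop=True)
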