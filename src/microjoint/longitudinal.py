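"""Negative-binomial mixed-effects longitudinal submodel.

Counts y_ij of a focal taxon are modelled as NB(mu_ij, theta) with

    log mu_ij = x_ij' beta + z_ij' b_i + log C_ij

where C_ij is the sample's library size (total reads, entering as a log
offset), beta are fixed effects, and b_i ~ MVN(0, D) are per-subject
random effects.  The parameterization has E[y] = mu and
Var(y) = mu + mu^2 / theta, with shape theta > 0 controlling
overdispersion.  The model-implied relative abundance
p_ij = mu_ij / C_ij = exp(x'beta + z'b) is the quantity that enters the
event hazard.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "nb_log_pmf",
    "linear_predictor",
    "fitted_relative_abundance",
    "NBGoodnessOfFit",
    "nb_goodness_of_fit",
]


def nb_log_pmf(y, mu, theta):
    """Log pmf of NB(mu, theta) with mean mu and Var = mu + mu^2/theta.

    Evaluated via log-gamma throughout, so it is finite for counts up to
    at least 1e6.  Vectorized; broadcasts like numpy ufuncs.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be a nonnegative integer count")
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if np.any(theta <= 0):
        raise ValueError("theta must be > 0")
    y = y.astype(float)
    log_denom = np.log(mu + theta)
    out = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
           + theta * (np.log(theta) - log_denom)
           + y * (np.log(mu) - log_denom))
    return out if out.shape else float(out)


def linear_predictor(design_fixed, beta, logC, design_random=None, b=None):
    """eta = x'beta + z'b + log C, elementwise over samples.

    ``design_fixed`` is (n, p); ``design_random`` (n, q) pairs with ``b``,
    either a single length-q vector (one subject) or an (n, q) matrix of
    per-row random coefficient values.
    """
    X = np.atleast_2d(np.asarray(design_fixed, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"fixed design has {X.shape[1]} columns but beta has "
            f"{beta.shape[0]} entries")
    eta = X @ beta + np.asarray(logC, dtype=float)
    if design_random is not None and b is not None:
        Z = np.atleast_2d(np.asarray(design_random, dtype=float))
        b = np.asarray(b, dtype=float)
        if b.ndim == 1:
            if Z.shape[1] != b.shape[0]:
                raise ValueError(
                    f"random design has {Z.shape[1]} columns but b has "
                    f"{b.shape[0]} entries")
            eta = eta + Z @ b
        else:
            if Z.shape != b.shape:
                raise ValueError("per-row b must match random design shape")
            eta = eta + np.sum(Z * b, axis=1)
    return eta


def fitted_relative_abundance(eta, logC):
    """p = mu / C = exp(eta - log C): the hazard's abundance covariate."""
    return np.exp(np.asarray(eta, dtype=float) - np.asarray(logC, dtype=float))


@dataclass
class NBGoodnessOfFit:
    """Diagnostic for whether one taxon's counts are NB-distributed."""

    theta_hat: float
    zero_frac_observed: float
    zero_frac_expected: float
    ks_statistic: float
    p_value: float
    suitable: bool
    reason: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def _fit_nb_fixed(y, X, logC, max_iter=200):
    """ML fit of a fixed-effects NB regression with offset.

    Alternates IRLS updates of beta (given theta) with Newton updates of
    log theta; adequate for a diagnostic fit.
    """
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(np.mean(y) + 0.5) - np.mean(logC)
    theta = 1.0
    for _ in range(max_iter):
        # IRLS for beta with NB working weights
        eta = X @ beta + logC
        mu = np.exp(np.clip(eta, -500, 500))
        wgt = mu / (1.0 + mu / theta)
        z = (eta - logC) + (y - mu) / mu
        WX = X * wgt[:, None]
        beta_new = np.linalg.solve(X.T @ WX + 1e-10 * np.eye(X.shape[1]),
                                   WX.T @ z)
        # Newton step on s = log theta
        mu = np.exp(np.clip(X @ beta_new + logC, -500, 500))

        def dll(th):
            from scipy.special import digamma
            return np.sum(digamma(y + th) - digamma(th) + np.log(th) + 1.0
                          - np.log(mu + th) - (y + th) / (mu + th))

        s = np.log(theta)
        g = dll(theta) * theta
        h = 1e-4
        g2 = (dll(np.exp(s + h)) * np.exp(s + h) - g) / h
        step = g / g2 if g2 < 0 else 0.5 * np.sign(g)
        s_new = s - np.clip(step, -1.0, 1.0) if g2 < 0 else s + np.clip(step, -1.0, 1.0)
        theta_new = float(np.clip(np.exp(s_new), 1e-3, 1e6))
        done = (np.max(np.abs(beta_new - beta)) < 1e-8
                and abs(np.log(theta_new / theta)) < 1e-8)
        beta, theta = beta_new, theta_new
        if done:
            break
    return beta, theta


def nb_goodness_of_fit(series, rng=None, alpha_level: float = 0.01,
                       zero_margin: float = 0.2) -> NBGoodnessOfFit:
    """Diagnose NB suitability of a taxon series.

    Fits a fixed-effects-only NB regression with library-size offset by
    maximum likelihood, then checks (a) observed vs expected zero fraction
    and (b) uniformity of randomized quantile residuals via a
    Kolmogorov-Smirnov test.  The series is flagged unsuitable when the KS
    p-value falls below ``alpha_level`` or the observed zero fraction
    exceeds the model-expected one by more than ``zero_margin``.

    Taxa flagged unsuitable (e.g. bimodal or zero-inflated abundances)
    should not be analysed with this joint model.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(series.y, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 observations for the diagnostic")
    if np.all(y == 0):
        return NBGoodnessOfFit(theta_hat=np.nan, zero_frac_observed=1.0,
                               zero_frac_expected=np.nan, ks_statistic=np.nan,
                               p_value=np.nan, suitable=False,
                               reason="unsuitable: degenerate")
    X = series.design_fixed
    logC = np.log(np.asarray(series.C, dtype=float))
    beta, theta = _fit_nb_fixed(y, X, logC)
    mu = np.exp(X @ beta + logC)

    # randomized quantile residuals: U = F(y-1) + V * pmf(y), V ~ U(0,1)
    p_nb = theta / (theta + mu)  # scipy's nbinom success prob
    cdf_lower = np.where(y > 0, stats.nbinom.cdf(y - 1, theta, p_nb), 0.0)
    pmf_y = stats.nbinom.pmf(y, theta, p_nb)
    u = cdf_lower + rng.uniform(size=n) * pmf_y
    u = np.clip(u, 1e-12, 1 - 1e-12)
    ks = stats.kstest(u, "uniform")

    zero_obs = float(np.mean(y == 0))
    zero_exp = float(np.mean((theta / (mu + theta)) ** theta))
    suitable = bool(ks.pvalue >= alpha_level
                    and zero_obs - zero_exp <= zero_margin)
    reason = "" if suitable else (
        f"unsuitable: KS p={ks.pvalue:.2e}" if ks.pvalue < alpha_level
        else f"unsuitable: excess zeros ({zero_obs:.2f} vs {zero_exp:.2f})")
    return NBGoodnessOfFit(theta_hat=float(theta),
                           zero_frac_observed=zero_obs,
                           zero_frac_expected=zero_exp,
                           ks_statistic=float(ks.statistic),
                           p_value=float(ks.pvalue),
                           suitable=suitable, reason=reason)
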