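"""Weighted negative binomial regression with a log link.

This module provides the M-step machinery for the mixture models: a
weighted maximum-likelihood fit of a negative binomial regression with a
single covariate (log detected genes), alternating between Fisher-scoring
updates of the regression coefficients and a univariate maximum-likelihood
update of the dispersion parameter.

The NB distribution is parameterized by its mean ``mu`` and size
(dispersion) ``nu`` so that ``Var(Y) = mu + mu**2 / nu``; ``nu -> inf``
recovers the Poisson distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "ComponentParams",
    "NBFit",
    "NBFitError",
    "nb_logpmf",
    "nb_pmf",
    "weighted_nb_loglik",
    "fit_weighted_nb",
]

#: Upper bound for the dispersion parameter; fits hitting it are flagged
#: (data indistinguishable from Poisson).
NU_CAP = 1e6
NU_FLOOR = 1e-4

#: Minimum effective sample size (sum of weights) required for a fit.
MIN_EFFECTIVE_N = 10.0


class NBFitError(ValueError):
    """Raised when a weighted NB fit cannot be carried out."""


@dataclass(frozen=True)
class ComponentParams:
    """Parameters of one mixture component: ``mu(x) = exp(alpha + beta*log x)``.

    ``beta`` is exactly 0 for intercept-only components.  ``link`` is fixed
    to ``"log"`` (recorded for serialization).
    """

    alpha: float
    beta: float
    nu: float
    link: str = "log"

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise NBFitError("non-finite regression coefficients")
        if not (self.nu > 0):
            raise NBFitError(f"dispersion must be positive, got {self.nu}")

    def mean(self, x) -> np.ndarray:
        """Predicted mean at detected-gene count(s) ``x``."""
        x = np.asarray(x, dtype=float)
        return np.exp(self.alpha + self.beta * np.log(x))

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "nu": self.nu, "link": self.link}


@dataclass
class NBFit:
    """Result of :func:`fit_weighted_nb` with convergence diagnostics."""

    params: ComponentParams
    loglik: float
    converged: bool
    n_iter: int
    nu_capped: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            loglik=self.loglik,
            converged=self.converged,
            n_iter=self.n_iter,
            nu_capped=self.nu_capped,
        )
        return d


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if np.any(yf != np.floor(yf)):
            raise ValueError("counts must be integers")
        y = yf.astype(np.int64)
    return y


def nb_logpmf(y, mu, nu) -> np.ndarray:
    """Log pmf of NB(mean=mu, size=nu), evaluated in log space.

    ``log P(Y=y) = lgamma(y+nu) - lgamma(nu) - lgamma(y+1)
    + nu*log(nu/(nu+mu)) + y*log(mu/(nu+mu))``
    """
    y = _validate_counts(y)
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(mu <= 0) or np.any(nu <= 0):
        raise ValueError("mu and nu must be positive")
    yf = np.asarray(y, dtype=float)
    log_ratio = np.log(mu + nu)
    return (
        gammaln(yf + nu)
        - gammaln(nu)
        - gammaln(yf + 1.0)
        + nu * (np.log(nu) - log_ratio)
        + yf * (np.log(mu) - log_ratio)
    )


def nb_pmf(y, mu, nu) -> np.ndarray:
    """Pmf of NB(mean=mu, size=nu); see :func:`nb_logpmf`."""
    return np.exp(nb_logpmf(y, mu, nu))


def weighted_nb_loglik(y, x, weights, params: ComponentParams) -> float:
    """Weighted log-likelihood sum_i w_i * log h(y_i | params, x_i)."""
    mu = params.mean(x)
    return float(np.sum(np.asarray(weights, dtype=float) * nb_logpmf(y, mu, params.nu)))


def _loglik_terms(y: np.ndarray, mu: np.ndarray, nu: float, w: np.ndarray) -> float:
    log_ratio = np.log(mu + nu)
    ll = (
        gammaln(y + nu)
        - gammaln(nu)
        + nu * (np.log(nu) - log_ratio)
        + y * (np.log(mu) - log_ratio)
    )
    # gammaln(y+1) omitted: constant in (coef, nu) alternation? It is constant
    # in the coefficients but also in nu, so drop it here and add it back when
    # reporting the final log-likelihood.
    return float(np.sum(w * ll))


def _irls(y, t, w, nu, alpha, beta, fix_beta_zero, max_iter=25, tol=1e-10):
    """Fisher scoring (IRLS) for (alpha, beta) at fixed dispersion.

    ``t`` is the covariate log(x).  Returns updated coefficients.
    """
    for _ in range(max_iter):
        eta = alpha + beta * t
        mu = np.exp(eta)
        # Fisher weights for log link: w * mu^2 / V(mu), V = mu + mu^2/nu
        fw = w * mu * nu / (nu + mu)
        z = eta + (y - mu) / mu
        if fix_beta_zero:
            denom = fw.sum()
            if denom <= 0:
                raise NBFitError("zero Fisher information")
            new_alpha, new_beta = float((fw * z).sum() / denom), 0.0
        else:
            s0 = fw.sum()
            s1 = (fw * t).sum()
            s2 = (fw * t * t).sum()
            b0 = (fw * z).sum()
            b1 = (fw * t * z).sum()
            det = s0 * s2 - s1 * s1
            if not np.isfinite(det) or abs(det) < 1e-300:
                raise NBFitError("singular Fisher information (constant covariate?)")
            new_alpha = float((s2 * b0 - s1 * b1) / det)
            new_beta = float((s0 * b1 - s1 * b0) / det)
        delta = abs(new_alpha - alpha) + abs(new_beta - beta)
        alpha, beta = new_alpha, new_beta
        if delta < tol:
            break
    return alpha, beta


def _update_nu(y, mu, w, nu_prev, nu_cap):
    """Maximize the weighted NB log-likelihood over log(nu) by Brent search."""

    def neg_ll(log_nu):
        return -_loglik_terms(y, mu, np.exp(log_nu), w)

    lo = np.log(NU_FLOOR)
    hi = np.log(nu_cap)
    # local bracket around the previous value speeds up the repeated calls
    # made from inside EM; fall back to the full range when the optimum sits
    # on the local boundary.
    if nu_prev is not None:
        llo = max(lo, np.log(nu_prev) - 2.0)
        lhi = min(hi, np.log(nu_prev) + 2.0)
        res = optimize.minimize_scalar(
            neg_ll, bounds=(llo, lhi), method="bounded", options={"xatol": 1e-8}
        )
        if res.x > llo + 1e-6 and res.x < lhi - 1e-6:
            return float(np.exp(res.x))
    res = optimize.minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    return float(np.exp(res.x))


def fit_weighted_nb(
    y,
    x,
    weights=None,
    fix_beta_zero: bool = False,
    tol: float = 1e-8,
    max_iter: int = 50,
    nu_cap: float = NU_CAP,
    min_effective_n: float = MIN_EFFECTIVE_N,
    init: ComponentParams | None = None,
) -> NBFit:
    """Weighted ML fit of an NB regression (log link) on log(x).

    Alternates (a) Fisher-scoring IRLS for the coefficients at fixed
    dispersion with (b) a univariate ML update of the dispersion at fixed
    coefficients, until the weighted log-likelihood changes by less than
    ``tol``.  With ``fix_beta_zero`` the slope is pinned to 0 and only the
    intercept is estimated.

    Parameters
    ----------
    y, x, weights
        Equal-length vectors: counts, detected genes (>=1) and fractional
        weights in [0, 1] (defaults to 1).
    init
        Optional warm start (used by the EM loop).

    Returns
    -------
    NBFit
        Fitted parameters plus diagnostics.  Non-convergence is flagged via
        ``converged=False``; a dispersion running away to the Poisson limit
        is clamped at ``nu_cap`` and flagged via ``nu_capped``.
    """
    y = _validate_counts(y).astype(float)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("detected-gene counts must be >= 1")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
    if not (len(y) == len(x) == len(w)):
        raise ValueError("y, x and weights must have equal length")
    ess = w.sum()
    if ess < min_effective_n:
        raise NBFitError(
            f"effective sample size {ess:.2f} below floor {min_effective_n}"
        )
    t = np.log(x)

    if init is not None:
        alpha, beta, nu = init.alpha, 0.0 if fix_beta_zero else init.beta, init.nu
    else:
        mu0 = max((w * y).sum() / ess, 1e-8)
        alpha, beta = float(np.log(mu0)), 0.0
        var0 = (w * (y - mu0) ** 2).sum() / ess
        nu = float(np.clip(mu0**2 / max(var0 - mu0, 1e-8), 1e-2, nu_cap))

    const = -float(np.sum(w * gammaln(y + 1.0)))
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        alpha, beta = _irls(y, t, w, nu, alpha, beta, fix_beta_zero)
        mu = np.exp(alpha + beta * t)
        if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
            raise NBFitError("predicted means left the positive range")
        nu = _update_nu(y, mu, w, nu, nu_cap)
        ll = _loglik_terms(y, mu, nu, w) + const
        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    # the bounded dispersion search stops within xatol of the boundary, so
    # flag anything in the top ~0.1% of the range as capped
    nu_capped = nu >= nu_cap * (1 - 1e-3)
    params = ComponentParams(alpha=alpha, beta=beta, nu=min(nu, nu_cap))
    return NBFit(
        params=params,
        loglik=prev_ll,
        converged=converged,
        n_iter=n_iter,
        nu_capped=nu_capped,
        message="" if converged else "max iterations reached",
    )
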