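"""Two-component NB (regression) mixture models fit by EM, per HTO.

For each HTO the counts are modeled as a mixture of a negative component
(background reads in droplets without a tagged cell) and a positive
component (droplets with a tagged cell), with component means optionally
regressed on log detected genes.  Three variants are fit:

- ``full``      — regression in both components,
- ``pos_only``  — regression in the positive component only (negative
                  slope pinned to 0),
- ``naive``     — no regression in either component.

Model selection minimizes the expected number of classification errors,
``sum_i min(p_i, 1 - p_i)``, over the droplets used for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .nb_glm import (
    ComponentParams,
    NBFitError,
    fit_weighted_nb,
    nb_logpmf,
)

__all__ = [
    "VARIANTS",
    "MixtureModel",
    "ComponentCollapseError",
    "fit_em",
    "posterior_positive",
    "hard_class",
    "expected_errors",
    "fit_best_model",
]

VARIANTS = ("full", "pos_only", "naive")

#: Mixture-proportion floor below which a component is declared collapsed.
PI_FLOOR = 1e-4

#: Mean fraction of expected errors above which the two fitted components
#: are declared degenerate (indistinguishable; the data look
#: one-component).  Well-separated mixtures sit orders of magnitude below.
DEGENERACY_ERROR_FRACTION = 0.2


class ComponentCollapseError(RuntimeError):
    """A mixture component vanished or the two components merged."""


@dataclass
class MixtureModel:
    """Fitted per-HTO mixture: proportions, two components, diagnostics."""

    pi: tuple[float, float]
    comp_neg: ComponentParams
    comp_pos: ComponentParams
    variant: str
    converged: bool
    loglik: float
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    hto_name: str | None = None
    selection: dict | None = None  # variant -> criterion (set by fit_best_model)

    def __post_init__(self) -> None:
        p1, p2 = self.pi
        if not (p1 > 0 and p2 > 0) or abs(p1 + p2 - 1.0) > 1e-9:
            raise ValueError("mixture proportions must be positive and sum to 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "naive" and (self.comp_neg.beta != 0 or self.comp_pos.beta != 0):
            raise ValueError("naive variant requires both slopes to be 0")
        if self.variant == "pos_only" and self.comp_neg.beta != 0:
            raise ValueError("pos_only variant requires the negative slope to be 0")

    def to_dict(self) -> dict:
        return {
            "hto_name": self.hto_name,
            "variant": self.variant,
            "pi_neg": self.pi[0],
            "pi_pos": self.pi[1],
            "neg": self.comp_neg.to_dict(),
            "pos": self.comp_pos.to_dict(),
            "converged": self.converged,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "selection": self.selection,
        }


def _component_logpdfs(model: MixtureModel, y, x):
    y = np.atleast_1d(y)
    x = np.atleast_1d(x)
    l1 = nb_logpmf(y, model.comp_neg.mean(x), model.comp_neg.nu)
    l2 = nb_logpmf(y, model.comp_pos.mean(x), model.comp_pos.nu)
    return l1, l2


def posterior_positive(model: MixtureModel, y, x):
    """P(droplet contains a tagged cell | y, x) with log-sum-exp stabilization."""
    l1, l2 = _component_logpdfs(model, y, x)
    a = np.log(model.pi[0]) + l1
    b = np.log(model.pi[1]) + l2
    denom = np.logaddexp(a, b)
    if np.any(~np.isfinite(denom)):
        raise FloatingPointError("both component densities underflowed")
    post = np.exp(b - denom)
    return post if np.ndim(y) or np.ndim(x) else float(post[0])


def hard_class(posterior):
    """MAP class: 1 iff posterior > 0.5 (ties classify as negative)."""
    return (np.asarray(posterior) > 0.5).astype(np.int8)


def expected_errors(model: MixtureModel, y_j, x, mask=None) -> float:
    """Expected number of misclassifications, sum_i min(p_i, 1 - p_i)."""
    p = np.atleast_1d(posterior_positive(model, y_j, x))
    if mask is not None:
        p = p[np.asarray(mask, dtype=bool)]
    return float(np.minimum(p, 1.0 - p).sum())


def _mixture_loglik(pi, l1, l2) -> float:
    return float(logsumexp(np.stack([np.log(pi[0]) + l1, np.log(pi[1]) + l2]), axis=0).sum())


def fit_em(
    y_j,
    x,
    init_positive,
    fit_mask=None,
    variant: str = "full",
    tol: float = 1e-6,
    max_iter: int = 100,
    hto_name: str | None = None,
) -> MixtureModel:
    """Fit one HTO's two-component mixture by EM.

    The E-step computes responsibilities from the current components; the
    M-step updates the proportions as mean responsibilities over the
    ``fit_mask`` droplets and refits each component by weighted NB
    regression with the responsibilities as weights (warm-started from the
    previous iterate).  Initial responsibilities are the hard labels from
    ``init_positive``.  Convergence is declared when the observed-data
    log-likelihood over the fitting droplets changes by less than ``tol``
    (relative); non-convergence returns ``converged=False`` rather than
    raising.

    Raises
    ------
    ComponentCollapseError
        If a mixture proportion drops below the floor, a component fit
        degenerates, or the two components end up indistinguishable.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    y = np.asarray(y_j)
    x = np.asarray(x, dtype=float)
    init_positive = np.asarray(init_positive, dtype=bool)
    m = len(y)
    if fit_mask is None:
        fit_mask = np.ones(m, dtype=bool)
    else:
        fit_mask = np.asarray(fit_mask, dtype=bool)
    who = f" for HTO {hto_name!r}" if hto_name else ""
    if not init_positive[fit_mask].any() or init_positive[fit_mask].all():
        raise ComponentCollapseError(f"initial clustering has an empty class{who}")

    yf = y[fit_mask]
    xf = x[fit_mask]
    r = init_positive[fit_mask].astype(float)

    fix_neg = variant in ("pos_only", "naive")
    fix_pos = variant == "naive"

    fit_neg = fit_pos = None
    pi = (0.5, 0.5)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # M-step
        pi2 = float(r.mean())
        if pi2 < PI_FLOOR or 1.0 - pi2 < PI_FLOOR:
            raise ComponentCollapseError(
                f"mixture proportion collapsed (pi_pos={pi2:.2e}){who}"
            )
        pi = (1.0 - pi2, pi2)
        try:
            fit_neg = fit_weighted_nb(
                yf, xf, weights=1.0 - r, fix_beta_zero=fix_neg,
                init=None if fit_neg is None else fit_neg.params,
            )
            fit_pos = fit_weighted_nb(
                yf, xf, weights=r, fix_beta_zero=fix_pos,
                init=None if fit_pos is None else fit_pos.params,
            )
        except NBFitError as err:
            raise ComponentCollapseError(f"component fit degenerated{who}: {err}") from err

        # E-step / convergence on the observed-data log-likelihood
        l1 = nb_logpmf(yf, fit_neg.params.mean(xf), fit_neg.params.nu)
        l2 = nb_logpmf(yf, fit_pos.params.mean(xf), fit_pos.params.nu)
        ll = _mixture_loglik(pi, l1, l2)
        a = np.log(pi[0]) + l1
        b = np.log(pi[1]) + l2
        r = np.exp(b - np.logaddexp(a, b))
        if trace and abs(ll - trace[-1]) < tol * (1.0 + abs(ll)):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

    comp_neg, comp_pos = fit_neg.params, fit_pos.params
    # undo label switching: the positive component must have the larger
    # fitted mean at the average covariate value
    x_ref = float(xf.mean())
    if comp_pos.mean(x_ref) < comp_neg.mean(x_ref):
        comp_neg, comp_pos = comp_pos, comp_neg
        pi = (pi[1], pi[0])
        if variant == "pos_only" and comp_neg.beta != 0:
            # a swap under pos_only would put the free slope on the negative
            # side; treat as a degenerate fit
            raise ComponentCollapseError(f"label switching under pos_only{who}")

    model = MixtureModel(
        pi=pi,
        comp_neg=comp_neg,
        comp_pos=comp_pos,
        variant=variant,
        converged=converged,
        loglik=trace[-1],
        n_iter=n_iter,
        loglik_trace=trace,
        hto_name=hto_name,
    )
    err_frac = expected_errors(model, yf, xf) / len(yf)
    if err_frac > DEGENERACY_ERROR_FRACTION:
        raise ComponentCollapseError(
            f"components are degenerate (expected error fraction "
            f"{err_frac:.2f}){who}: data look one-component"
        )
    return model


def fit_best_model(
    y_j,
    x,
    init_positive,
    fit_mask=None,
    variants=VARIANTS,
    tol: float = 1e-6,
    max_iter: int = 100,
    hto_name: str | None = None,
) -> MixtureModel:
    """Fit all requested variants and return the expected-error minimizer.

    The criterion is evaluated over the ``fit_mask`` (non-outlier)
    droplets.  Variants that collapse or fail to converge are excluded; if
    every variant fails the error for this HTO propagates.
    """
    criteria: dict[str, float | None] = {}
    candidates: list[tuple[float, MixtureModel]] = []
    last_error: Exception | None = None
    for variant in variants:
        try:
            model = fit_em(
                y_j, x, init_positive, fit_mask=fit_mask, variant=variant,
                tol=tol, max_iter=max_iter, hto_name=hto_name,
            )
        except ComponentCollapseError as err:
            criteria[variant] = None
            last_error = err
            continue
        if not model.converged:
            criteria[variant] = None
            continue
        crit = expected_errors(model, y_j, x, mask=fit_mask)
        criteria[variant] = crit
        candidates.append((crit, model))
    if not candidates:
        who = f" for HTO {hto_name!r}" if hto_name else ""
        raise ComponentCollapseError(
            f"all mixture model variants failed{who}"
            + (f": {last_error}" if last_error else "")
        )
    best = min(candidates, key=lambda t: t[0])[1]
    best.selection = criteria
    return best
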