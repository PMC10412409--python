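"""Overlap-score quality metric for fitted HTO mixtures.

The overlap score is the shared probability mass of the negative and
positive component pmfs, each evaluated at the component's posterior-
weighted mean number of detected genes (ignored for naive models).  It
lies in (0, 1], is independent of the mixture proportions, and small
values indicate well-separated (high-quality) HTO signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import MixtureModel
from .nb_glm import ComponentParams, nb_pmf

__all__ = ["QualityReport", "weighted_mean_genes", "overlap_score", "hto_quality", "quality_frame"]

TAIL_MASS = 1e-9


@dataclass(frozen=True)
class QualityReport:
    hto_name: str
    variant: str
    ovs: float
    xbar_neg: float
    xbar_pos: float
    pi_pos: float
    converged: bool
    truncation_mass: float

    def __post_init__(self) -> None:
        if not (0 < self.ovs <= 1 + 1e-9):
            raise ValueError(f"overlap score out of range: {self.ovs}")
        if not (self.truncation_mass < 1e-8):
            raise ValueError(f"truncation mass too large: {self.truncation_mass}")


def weighted_mean_genes(x, posteriors, outlier_mask=None) -> tuple[float, float]:
    """Posterior-weighted mean detected genes of each component.

    Outlier droplets are removed before averaging.  Returns
    ``(xbar_neg, xbar_pos)``; an effectively empty component (all
    posteriors ~0 or ~1) is an error rather than a NaN.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(posteriors, dtype=float)
    if outlier_mask is not None:
        keep = ~np.asarray(outlier_mask, dtype=bool)
        x, p = x[keep], p[keep]
    w_pos = p.sum()
    w_neg = (1.0 - p).sum()
    if w_pos < 1e-9 or w_neg < 1e-9:
        raise ValueError(
            "cannot compute weighted mean genes: one component carries "
            "(numerically) no posterior mass"
        )
    return float(((1.0 - p) * x).sum() / w_neg), float((p * x).sum() / w_pos)


def _truncation_point(mu: float, nu: float) -> int:
    return int(stats.nbinom.ppf(1.0 - TAIL_MASS, nu, nu / (nu + mu)))


def overlap_score(
    model: MixtureModel,
    xbar_neg: float | None = None,
    xbar_pos: float | None = None,
) -> tuple[float, float]:
    """Shared probability mass of the two fitted components.

    Sums ``min(h(z | neg, xbar_neg), h(z | pos, xbar_pos))`` over z from 0
    up to a truncation point where both components' residual tail mass is
    below 1e-9; the larger residual is returned alongside the score.  For
    naive models the component means do not depend on x and the ``xbar``
    arguments are ignored.
    """
    if model.variant == "naive":
        mu1 = float(np.exp(model.comp_neg.alpha))
        mu2 = float(np.exp(model.comp_pos.alpha))
    else:
        if xbar_neg is None or xbar_pos is None:
            raise ValueError("regression models need xbar_neg and xbar_pos")
        mu1 = float(model.comp_neg.mean(xbar_neg))
        mu2 = float(model.comp_pos.mean(xbar_pos))
    nu1, nu2 = model.comp_neg.nu, model.comp_pos.nu
    z_max = max(_truncation_point(mu1, nu1), _truncation_point(mu2, nu2))
    z = np.arange(z_max + 1)
    h1 = nb_pmf(z, mu1, nu1)
    h2 = nb_pmf(z, mu2, nu2)
    # clamp away from exact 0 (possible via floating-point underflow when
    # the components' effective supports are disjoint) to keep ovs in (0, 1]
    ovs = max(float(np.minimum(h1, h2).sum()), 1e-300)
    residual = float(
        max(
            stats.nbinom.sf(z_max, nu1, nu1 / (nu1 + mu1)),
            stats.nbinom.sf(z_max, nu2, nu2 / (nu2 + mu2)),
        )
    )
    return min(ovs, 1.0), residual


def hto_quality(model: MixtureModel, x, posteriors, outlier_mask=None) -> QualityReport:
    """Assemble the per-HTO quality report from a fitted model."""
    if model.variant == "naive":
        # the means are covariate-free but the weighted x means are still
        # informative diagnostics
        xbar_neg, xbar_pos = weighted_mean_genes(x, posteriors, outlier_mask)
        ovs, resid = overlap_score(model)
    else:
        xbar_neg, xbar_pos = weighted_mean_genes(x, posteriors, outlier_mask)
        ovs, resid = overlap_score(model, xbar_neg, xbar_pos)
    return QualityReport(
        hto_name=model.hto_name or "",
        variant=model.variant,
        ovs=ovs,
        xbar_neg=xbar_neg,
        xbar_pos=xbar_pos,
        pi_pos=model.pi[1],
        converged=model.converged,
        truncation_mass=resid,
    )


def quality_frame(reports: list[QualityReport]) -> pd.DataFrame:
    """Tabulate quality reports for TSV output."""
    return pd.DataFrame(
        {
            "hto_name": [r.hto_name for r in reports],
            "variant": [r.variant for r in reports],
            "ovs": [r.ovs for r in reports],
            "xbar_neg": [r.xbar_neg for r in reports],
            "xbar_pos": [r.xbar_pos for r in reports],
            "pi_pos": [r.pi_pos for r in reports],
            "converged": [r.converged for r in reports],
        }
    )
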