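"""End-to-end demultiplexing: preprocessing, per-HTO model fits, joint calls."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import DropletAssignment, classify_droplets, default_acceptance
from .hashing_data import HashingExperiment, InitClustering, preprocess
from .mixture import MixtureModel, fit_best_model, fit_em, posterior_positive
from .quality import QualityReport, hto_quality

__all__ = ["DemuxResult", "demultiplex"]


@dataclass
class DemuxResult:
    """Everything produced by one demultiplexing run."""

    assignments: list[DropletAssignment]
    posteriors: np.ndarray  # m x n
    models: list[MixtureModel]
    quality: list[QualityReport]
    clustering: InitClustering
    p_acpt: float

    @property
    def labels(self) -> np.ndarray:
        return np.array([a.label for a in self.assignments])


def demultiplex(
    experiment: HashingExperiment,
    p_acpt: float | None = None,
    variant: str = "auto",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> DemuxResult:
    """Run the full pipeline on a hashing experiment.

    For each HTO: initial k-means clustering and outlier flagging, mixture
    fitting (all three variants with expected-error model selection when
    ``variant="auto"``, otherwise the forced variant), then posterior
    computation for every droplet (outliers included).  Per-droplet calls
    combine the per-HTO posteriors with acceptance threshold ``p_acpt``
    (default ``0.9 ** n_htos``).
    """
    clustering = preprocess(experiment, seed=seed)
    m, n = experiment.counts.shape
    x = experiment.detected_genes
    posteriors = np.zeros((m, n))
    models: list[MixtureModel] = []
    reports: list[QualityReport] = []
    for j, name in enumerate(experiment.hto_names):
        y_j = experiment.counts[:, j]
        fit_mask = ~clustering.outlier[:, j]
        init = clustering.positive[:, j]
        if variant == "auto":
            model = fit_best_model(
                y_j, x, init, fit_mask=fit_mask, tol=tol, max_iter=max_iter,
                hto_name=str(name),
            )
        else:
            model = fit_em(
                y_j, x, init, fit_mask=fit_mask, variant=variant, tol=tol,
                max_iter=max_iter, hto_name=str(name),
            )
        posteriors[:, j] = posterior_positive(model, y_j, x)
        models.append(model)
        reports.append(
            hto_quality(model, x, posteriors[:, j], outlier_mask=clustering.outlier[:, j])
        )
    if p_acpt is None:
        p_acpt = default_acceptance(n)
    assignments = classify_droplets(
        posteriors, experiment.hto_names, droplet_ids=experiment.droplet_ids, p_acpt=p_acpt
    )
    return DemuxResult(
        assignments=assignments,
        posteriors=posteriors,
        models=models,
        quality=reports,
        clustering=clustering,
        p_acpt=p_acpt,
    )
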