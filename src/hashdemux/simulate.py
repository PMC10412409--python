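"""Synthetic hashing data with ground truth, benchmark transforms and metrics.

The generator is the sampling counterpart of the fitted model: per-droplet
detected genes from a stated law, true classes from stated probabilities,
and NB counts whose means depend log-linearly on detected genes, with
separate signal (tagged) and background parameters per HTO.  Benchmark
transforms attenuate the tagged signal by a scaling factor and inject
artificial multiplets by merging single-sample droplets; metrics score an
assignment vector against the ground-truth class matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import DropletAssignment
from .hashing_data import HashingExperiment
from .nb_glm import ComponentParams

__all__ = [
    "NBRegParams",
    "SimulatedDataset",
    "BenchmarkResult",
    "lognormal_gene_law",
    "nbreg_params",
    "generate_dataset",
    "attenuate_signal",
    "merge_doublets",
    "benchmark_metrics",
]


@dataclass(frozen=True)
class NBRegParams:
    """Generating NB regression parameters: mean(x) = exp(alpha + beta*log x)."""

    alpha: float
    beta: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.nu > 0):
            raise ValueError(f"dispersion must be positive, got {self.nu}")

    def mean(self, x) -> np.ndarray:
        return np.exp(self.alpha + self.beta * np.log(np.asarray(x, dtype=float)))

    def as_component(self) -> ComponentParams:
        return ComponentParams(alpha=self.alpha, beta=self.beta, nu=self.nu)


def nbreg_params(mean_at_ref: float, beta: float, nu: float, x_ref: float = 1800.0) -> NBRegParams:
    """Parameters with a given mean at the reference detected-gene count."""
    if mean_at_ref <= 0 or x_ref <= 0:
        raise ValueError("reference mean and x_ref must be positive")
    return NBRegParams(alpha=float(np.log(mean_at_ref) - beta * np.log(x_ref)), beta=beta, nu=nu)


def lognormal_gene_law(median: float = 1800.0, sigma: float = 0.5, floor: int = 50):
    """Detected-gene sampler: lognormal with the given median, floored."""

    def sample(rng: np.random.Generator, m: int) -> np.ndarray:
        x = rng.lognormal(mean=np.log(median), sigma=sigma, size=m)
        return np.maximum(np.rint(x).astype(np.int64), floor)

    return sample


@dataclass(frozen=True)
class SimulatedDataset:
    """Synthetic experiment plus its ground-truth class matrix."""

    experiment: HashingExperiment
    truth: np.ndarray  # binary m x n
    params: dict

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth)
        if truth.shape != self.experiment.counts.shape:
            raise ValueError("truth matrix must match the count matrix shape")
        if not np.isin(truth, (0, 1)).all():
            raise ValueError("truth matrix must be binary")
        object.__setattr__(self, "truth", truth.astype(np.int8))


def _per_hto(params, n: int) -> list[NBRegParams]:
    if isinstance(params, NBRegParams):
        return [params] * n
    params = list(params)
    if len(params) != n:
        raise ValueError(f"expected {n} per-HTO parameter sets, got {len(params)}")
    return params


def generate_dataset(
    m: int,
    n: int,
    signal_params,
    background_params,
    class_probs,
    msm_prob: float = 0.0,
    gene_count_law=None,
    seed: int = 0,
) -> SimulatedDataset:
    """Draw a synthetic hashing experiment with known classes.

    ``class_probs`` gives the probability of a droplet being an SSD of each
    of the ``n`` samples; ``msm_prob`` the probability of a two-sample
    multiplet (samples drawn uniformly without replacement); the remainder
    are negative droplets.  Counts are NB with mean
    ``exp(alpha + beta*log x)`` using the signal parameters where the truth
    matrix is 1 and the background parameters elsewhere.  Fully
    reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    class_probs = np.asarray(class_probs, dtype=float)
    if class_probs.shape != (n,) or np.any(class_probs < 0):
        raise ValueError("class_probs must be n non-negative probabilities")
    if not (0 <= msm_prob <= 1) or class_probs.sum() + msm_prob > 1 + 1e-9:
        raise ValueError("class probabilities and msm_prob must sum to at most 1")
    if n == 1 and msm_prob > 0:
        raise ValueError("multiplets need at least two samples")
    signal = _per_hto(signal_params, n)
    background = _per_hto(background_params, n)
    if gene_count_law is None:
        gene_count_law = lognormal_gene_law()

    x = gene_count_law(rng, m)

    p_neg = max(1.0 - class_probs.sum() - msm_prob, 0.0)
    pvec = np.concatenate([class_probs, [msm_prob, p_neg]])
    pvec = pvec / pvec.sum()
    draw = rng.choice(n + 2, size=m, p=pvec)
    truth = np.zeros((m, n), dtype=np.int8)
    for j in range(n):
        truth[draw == j, j] = 1
    for i in np.flatnonzero(draw == n):
        pair = rng.choice(n, size=2, replace=False)
        truth[i, pair] = 1

    counts = np.zeros((m, n), dtype=np.int64)
    for j in range(n):
        tagged = truth[:, j] == 1
        for params, mask in ((signal[j], tagged), (background[j], ~tagged)):
            if not mask.any():
                continue
            mu = params.mean(x[mask])
            p = params.nu / (params.nu + mu)
            counts[mask, j] = rng.negative_binomial(params.nu, p)

    experiment = HashingExperiment(
        counts=counts,
        detected_genes=x,
        droplet_ids=np.array([f"droplet{i:06d}" for i in range(m)], dtype=object),
        hto_names=np.array([f"HTO{j + 1}" for j in range(n)], dtype=object),
    )
    params = {
        "m": m,
        "n": n,
        "seed": seed,
        "msm_prob": msm_prob,
        "class_probs": class_probs.tolist(),
        "signal": [vars(p) for p in signal],
        "background": [vars(p) for p in background],
    }
    return SimulatedDataset(experiment=experiment, truth=truth, params=params)


def attenuate_signal(
    experiment: HashingExperiment, truth, s: float
) -> HashingExperiment:
    """Scale tagged-HTO counts by ``s`` (rounded); background is untouched."""
    if not (0 < s <= 1):
        raise ValueError(f"scaling factor must lie in (0, 1], got {s}")
    truth = np.asarray(truth)
    counts = experiment.counts.copy()
    tagged = truth == 1
    counts[tagged] = np.rint(s * counts[tagged]).astype(np.int64)
    return HashingExperiment(
        counts=counts,
        detected_genes=experiment.detected_genes,
        droplet_ids=experiment.droplet_ids,
        hto_names=experiment.hto_names,
    )


def merge_doublets(
    experiment: HashingExperiment, truth, n_doublets: int, seed: int = 0
) -> SimulatedDataset:
    """Append artificial multiplets built by averaging two SSDs.

    Each doublet merges two single-sample droplets from different samples:
    its HTO counts and detected-gene count are the rounded averages of the
    sources, and its truth row is the OR of theirs.  Source droplets are
    kept in the dataset.
    """
    truth = np.asarray(truth)
    m, n = experiment.counts.shape
    ssd_rows = np.flatnonzero(truth.sum(axis=1) == 1)
    ssd_sample = truth[ssd_rows].argmax(axis=1)
    if len(np.unique(ssd_sample)) < 2:
        raise ValueError("need SSDs from at least two different samples to merge")
    if n_doublets == 0:
        return SimulatedDataset(
            experiment=experiment,
            truth=truth.astype(np.int8),
            params={"n_doublets": 0, "seed": seed},
        )
    rng = np.random.default_rng(seed)
    new_counts, new_genes, new_truth = [], [], []
    for _ in range(n_doublets):
        while True:
            a, b = rng.choice(len(ssd_rows), size=2, replace=False)
            if ssd_sample[a] != ssd_sample[b]:
                break
        ia, ib = ssd_rows[a], ssd_rows[b]
        new_counts.append(
            np.rint((experiment.counts[ia] + experiment.counts[ib]) / 2.0).astype(np.int64)
        )
        new_genes.append(
            max(
                int(
                    np.rint(
                        (experiment.detected_genes[ia] + experiment.detected_genes[ib]) / 2.0
                    )
                ),
                1,
            )
        )
        new_truth.append(truth[ia] | truth[ib])
    merged = HashingExperiment(
        counts=np.vstack([experiment.counts, np.asarray(new_counts, dtype=np.int64)]),
        detected_genes=np.concatenate([experiment.detected_genes, new_genes]),
        droplet_ids=np.concatenate(
            [
                experiment.droplet_ids,
                [f"doublet{i:05d}" for i in range(n_doublets)],
            ]
        ),
        hto_names=experiment.hto_names,
    )
    full_truth = np.vstack([truth, np.asarray(new_truth)]).astype(np.int8)
    return SimulatedDataset(
        experiment=merged,
        truth=full_truth,
        params={"n_doublets": n_doublets, "seed": seed},
    )


@dataclass(frozen=True)
class BenchmarkResult:
    """SSD/MSM performance metrics of an assignment against ground truth.

    ``precision_ssd`` counts predicted SSDs whose sample is exactly right;
    ``sensitivity_ssd`` counts true SSDs recovered as any SSD; ``f_ssd`` is
    their harmonic mean.  Metrics are ``None`` when their denominator is
    empty (e.g. no predicted SSDs) rather than 0.
    """

    precision_ssd: float | None
    sensitivity_ssd: float | None
    f_ssd: float | None
    precision_msm: float | None
    msm_proportion: float
    confusion: dict[tuple[str, str], int]

    def to_dict(self) -> dict:
        return {
            "precision_ssd": self.precision_ssd,
            "sensitivity_ssd": self.sensitivity_ssd,
            "f_ssd": self.f_ssd,
            "precision_msm": self.precision_msm,
            "msm_proportion": self.msm_proportion,
            "confusion": {f"{t}->{p}": v for (t, p), v in sorted(self.confusion.items())},
        }


def _true_label(row: np.ndarray) -> str:
    k = int(row.sum())
    return "negative" if k == 0 else ("SSD" if k == 1 else "MSM")


def benchmark_metrics(assignments: list[DropletAssignment], truth) -> BenchmarkResult:
    """Score droplet assignments against the ground-truth class matrix."""
    truth = np.asarray(truth)
    m = truth.shape[0]
    if len(assignments) != m:
        raise ValueError("assignments and truth must cover the same droplets")

    pred_ssd = pred_msm = 0
    pred_ssd_correct = 0
    pred_msm_true = 0
    true_ssd = truth.sum(axis=1) == 1
    recovered_ssd = 0
    confusion: dict[tuple[str, str], int] = {}
    for i, a in enumerate(assignments):
        t = _true_label(truth[i])
        confusion[(t, a.label)] = confusion.get((t, a.label), 0) + 1
        if a.label == "SSD":
            pred_ssd += 1
            if np.array_equal(np.asarray(a.c_hat), truth[i]):
                pred_ssd_correct += 1
            if true_ssd[i]:
                recovered_ssd += 1
        elif a.label == "MSM":
            pred_msm += 1
            if t == "MSM":
                pred_msm_true += 1

    n_true_ssd = int(true_ssd.sum())
    precision = pred_ssd_correct / pred_ssd if pred_ssd else None
    sensitivity = recovered_ssd / n_true_ssd if n_true_ssd else None
    if precision is not None and sensitivity is not None and (precision + sensitivity) > 0:
        f = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f = None
    return BenchmarkResult(
        precision_ssd=precision,
        sensitivity_ssd=sensitivity,
        f_ssd=f,
        precision_msm=pred_msm_true / pred_msm if pred_msm else None,
        msm_proportion=pred_msm / m,
        confusion=confusion,
    )
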