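"""Data model and preprocessing for cell-hashing experiments.

A :class:`HashingExperiment` bundles the droplets-by-HTO count matrix, the
per-droplet number of detected genes (the regression covariate) and the
droplet/HTO identifiers.  Preprocessing mirrors the model-fitting recipe:
per-HTO k-means initial clustering on log counts and IQR-based outlier
flags.  Flagged droplets are excluded from model fitting only; they are
still classified downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from sklearn.cluster import KMeans

__all__ = [
    "HashingExperiment",
    "InitClustering",
    "detected_genes_from_rna",
    "initial_clusters",
    "flag_outliers",
    "preprocess",
    "read_10x_mtx",
    "read_dense",
    "write_10x_mtx",
    "write_flags_tsv",
]


@dataclass(frozen=True)
class HashingExperiment:
    """Droplets-by-HTO counts plus the detected-gene covariate.

    Invariants enforced at construction: non-negative integer counts,
    detected_genes >= 1 for every droplet (the covariate enters a
    logarithm), unique droplet ids, at least 2 droplets and 1 HTO.
    """

    counts: np.ndarray
    detected_genes: np.ndarray
    droplet_ids: np.ndarray
    hto_names: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (droplets x HTOs)")
        if not np.issubdtype(counts.dtype, np.integer):
            cf = counts.astype(float)
            if np.any(cf != np.floor(cf)):
                raise ValueError("counts must be integers")
            counts = cf.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        m, n = counts.shape
        if m < 2 or n < 1:
            raise ValueError("need at least 2 droplets and 1 HTO")
        genes = np.asarray(self.detected_genes, dtype=np.int64)
        if genes.shape != (m,):
            raise ValueError("detected_genes length must match droplet count")
        if np.any(genes < 1):
            bad = np.asarray(self.droplet_ids)[genes < 1]
            raise ValueError(
                "droplets with zero detected genes are not admissible "
                f"(covariate enters a logarithm): {', '.join(map(str, bad[:5]))}"
            )
        ids = np.asarray(self.droplet_ids, dtype=object).astype(str)
        if ids.shape != (m,):
            raise ValueError("droplet_ids length must match droplet count")
        if len(set(ids)) != m:
            raise ValueError("droplet_ids must be unique")
        names = np.asarray(self.hto_names, dtype=object).astype(str)
        if names.shape != (n,):
            raise ValueError("hto_names length must match HTO count")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "detected_genes", genes)
        object.__setattr__(self, "droplet_ids", ids)
        object.__setattr__(self, "hto_names", names)

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[0]

    @property
    def n_htos(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class InitClustering:
    """Per-HTO initial positive clusters and outlier flags (droplets x HTOs)."""

    positive: np.ndarray  # bool, m x n
    outlier: np.ndarray  # bool, m x n

    def __post_init__(self) -> None:
        pos = np.asarray(self.positive, dtype=bool)
        out = np.asarray(self.outlier, dtype=bool)
        if pos.shape != out.shape or pos.ndim != 2:
            raise ValueError("positive and outlier masks must share an m x n shape")
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "outlier", out)


def detected_genes_from_rna(rna_counts, droplet_ids=None) -> np.ndarray:
    """Number of genes with at least one read, per droplet (matrix row).

    Raises a hard error naming the droplet if any row has no detected gene.
    """
    if sparse.issparse(rna_counts):
        genes = np.asarray((rna_counts > 0).sum(axis=1)).ravel().astype(np.int64)
    else:
        arr = np.asarray(rna_counts)
        if arr.ndim != 2:
            raise ValueError("rna_counts must be a 2-D matrix (droplets x genes)")
        if np.any(arr < 0):
            raise ValueError("rna_counts must be non-negative")
        genes = (arr > 0).sum(axis=1).astype(np.int64)
    if np.any(genes == 0):
        idx = np.flatnonzero(genes == 0)
        if droplet_ids is not None:
            who = ", ".join(str(np.asarray(droplet_ids)[i]) for i in idx[:5])
        else:
            who = ", ".join(f"row {i}" for i in idx[:5])
        raise ValueError(f"droplet(s) with zero detected genes: {who}")
    return genes


def initial_clusters(y_j, seed: int, n_init: int = 10) -> np.ndarray:
    """Initial positive/negative split of one HTO's counts.

    k-means with k=2 on log(y+1); the cluster with the larger mean count on
    the count scale is the positive cluster.  Deterministic given ``seed``.
    """
    y = np.asarray(y_j, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("y_j must be a vector of length >= 2")
    if np.all(y == y[0]):
        raise ValueError("HTO has no variation: constant counts cannot be clustered")
    logy = np.log1p(y).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(logy)
    mean0 = y[labels == 0].mean()
    mean1 = y[labels == 1].mean()
    positive_label = 0 if mean0 > mean1 else 1
    return labels == positive_label


def _tukey_upper_fence(v: np.ndarray) -> float:
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return q3 + 1.5 * (q3 - q1)


def flag_outliers(y_j, x, positive_mask) -> np.ndarray:
    """Tukey-fence outlier flags for one HTO.

    A droplet is flagged when it sits in the positive cluster with an HTO
    count above Q3 + 1.5*IQR of the positive cluster's counts, or when its
    detected-gene count exceeds Q3 + 1.5*IQR of all droplets' detected
    genes.  Quantiles use linear interpolation.
    """
    y = np.asarray(y_j, dtype=float)
    x = np.asarray(x, dtype=float)
    pos = np.asarray(positive_mask, dtype=bool)
    if not (len(y) == len(x) == len(pos)):
        raise ValueError("y_j, x and positive_mask must have equal length")
    out = np.zeros(len(y), dtype=bool)
    if pos.any():
        fence_y = _tukey_upper_fence(y[pos])
        out |= pos & (y > fence_y)
    fence_x = _tukey_upper_fence(x)
    out |= x > fence_x
    return out


def preprocess(experiment: HashingExperiment, seed: int = 0) -> InitClustering:
    """Run per-HTO initial clustering and outlier flagging."""
    m, n = experiment.counts.shape
    positive = np.zeros((m, n), dtype=bool)
    outlier = np.zeros((m, n), dtype=bool)
    for j in range(n):
        y_j = experiment.counts[:, j]
        positive[:, j] = initial_clusters(y_j, seed=seed)
        outlier[:, j] = flag_outliers(y_j, experiment.detected_genes, positive[:, j])
    return InitClustering(positive=positive, outlier=outlier)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv_column(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_features(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    cols = ["id", "name", "feature_type"][: df.shape[1]]
    df.columns = cols + [f"extra{i}" for i in range(df.shape[1] - len(cols))]
    if "name" not in df.columns:
        df["name"] = df["id"]
    return df


def read_10x_mtx(
    directory: str,
    detected_genes=None,
    hto_names=None,
    feature_type: str | None = None,
    matrix_file: str = "matrix.mtx",
    barcodes_file: str = "barcodes.tsv",
    features_file: str = "features.tsv",
) -> HashingExperiment:
    """Read a Matrix Market matrix with barcode/feature sidecars.

    Orientation (droplets-by-features vs features-by-droplets) is detected
    by matching the matrix dimensions to the sidecar lengths; an ambiguous
    square matrix is an error.  HTO features are selected by ``hto_names``
    or by ``feature_type`` (third sidecar column); with neither, all
    features are taken as HTOs.

    ``detected_genes`` must be supplied (vector aligned with barcodes)
    unless the selected features leave gene features behind, in which case
    it can be computed with :func:`detected_genes_from_rna` by the caller.
    """
    mat = mmread(os.path.join(directory, matrix_file))
    mat = sparse.csr_matrix(mat)
    barcodes = _read_tsv_column(os.path.join(directory, barcodes_file))
    features = _read_features(os.path.join(directory, features_file))
    nb, nf = len(barcodes), len(features)
    r, c = mat.shape
    if (r, c) == (nb, nf) and (r, c) == (nf, nb):
        raise ValueError(
            "matrix orientation is ambiguous: barcode and feature counts match "
            "both dimensions"
        )
    if (r, c) == (nf, nb):
        mat = mat.T.tocsr()
    elif (r, c) != (nb, nf):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (barcodes={nb}, "
            f"features={nf}) orientation"
        )
    if hto_names is not None:
        wanted = [str(h) for h in hto_names]
        missing = set(wanted) - set(features["name"])
        if missing:
            raise ValueError(f"HTO feature(s) not found: {sorted(missing)}")
        sel = features["name"].isin(wanted).to_numpy()
    elif feature_type is not None:
        if "feature_type" not in features.columns:
            raise ValueError("features file has no feature_type column")
        sel = (features["feature_type"] == feature_type).to_numpy()
        if not sel.any():
            raise ValueError(f"no features of type {feature_type!r}")
    else:
        sel = np.ones(nf, dtype=bool)
    counts = np.asarray(mat[:, np.flatnonzero(sel)].todense())
    if detected_genes is None:
        raise ValueError("detected_genes vector is required")
    return HashingExperiment(
        counts=counts.astype(np.int64),
        detected_genes=np.asarray(detected_genes, dtype=np.int64),
        droplet_ids=np.asarray(barcodes, dtype=object),
        hto_names=features.loc[sel, "name"].to_numpy(dtype=object),
    )


def read_dense(path: str, detected_genes=None, sep: str | None = None) -> HashingExperiment:
    """Read a dense TSV/CSV with droplet rows, HTO columns and an id index."""
    if sep is None:
        sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if detected_genes is None:
        if "detected_genes" not in df.columns:
            raise ValueError(
                "detected_genes vector required (or a 'detected_genes' column)"
            )
        detected_genes = df.pop("detected_genes").to_numpy()
    return HashingExperiment(
        counts=df.to_numpy(),
        detected_genes=np.asarray(detected_genes, dtype=np.int64),
        droplet_ids=df.index.to_numpy(dtype=object),
        hto_names=df.columns.to_numpy(dtype=object),
    )


def write_10x_mtx(experiment: HashingExperiment, directory: str) -> None:
    """Write counts as features-by-barcodes Matrix Market plus sidecars.

    Also writes ``detected_genes.tsv`` (droplet id, value) so the layout is
    self-contained for :func:`read_10x_mtx`.
    """
    os.makedirs(directory, exist_ok=True)
    mat = sparse.coo_matrix(experiment.counts.T)
    mmwrite(os.path.join(directory, "matrix.mtx"), mat, field="integer")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{b}\n" for b in experiment.droplet_ids)
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        fh.writelines(f"{h}\t{h}\tAntibody Capture\n" for h in experiment.hto_names)
    pd.DataFrame(
        {"droplet_id": experiment.droplet_ids, "detected_genes": experiment.detected_genes}
    ).to_csv(os.path.join(directory, "detected_genes.tsv"), sep="\t", index=False)


def write_flags_tsv(
    experiment: HashingExperiment, clustering: InitClustering, path: str
) -> None:
    """Write per-droplet preprocessing flags (one column pair per HTO)."""
    data = {"droplet_id": experiment.droplet_ids}
    for j, name in enumerate(experiment.hto_names):
        data[f"positive_{name}"] = clustering.positive[:, j].astype(int)
        data[f"outlier_{name}"] = clustering.outlier[:, j].astype(int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
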