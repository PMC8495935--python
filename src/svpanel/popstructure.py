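"""SNP-based population structure: k-means with silhouette-selected k, PCA.

Genotypes are coded as 0/1/2 alternate-allele dosage with mean imputation
of missing calls, then clustered with k-means (Euclidean distance, multiple
random restarts).  The number of clusters is chosen by maximizing the
average silhouette width across a candidate range.  Cluster labels are
renumbered by decreasing cluster size so that label identity is stable
across runs and sample orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

DEFAULT_K_RANGE = range(2, 16)
DEFAULT_N_RESTARTS = 25


@dataclass
class ClusterAssignment:
    """Hard cluster labels (1..k) for every sample, with selection evidence."""

    sample_ids: list[str]
    labels: np.ndarray  # 1..k
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    pca_coords: np.ndarray | None = None
    pca_variance_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size != len(self.sample_ids):
            raise ValueError("labels and sample_ids differ in length")
        if self.labels.size and not (
            self.labels.min() >= 1 and self.labels.max() <= self.k
        ):
            raise ValueError("labels must lie in 1..k")

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})


def read_snp_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a biallelic SNP VCF into a sites x samples dosage matrix.

    Dosage is the alternate-allele count 0/1/2 with NaN for missing calls.
    Returns (dosage, positions, sample_ids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, chroms, starts = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = np.asarray(v.gt_types, dtype=float)  # 0 ref,1 het,2 unknown,3 alt
        dosage = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dosage)
        chroms.append(v.CHROM)
        starts.append(int(v.POS))
    dosage = np.array(rows) if rows else np.zeros((0, len(samples)))
    positions = pd.DataFrame({"chrom": chroms, "start": starts})
    return dosage, positions, samples


def encode_snp_matrix(dosage: np.ndarray) -> np.ndarray:
    """Samples x sites numeric matrix for clustering.

    Input is sites x samples dosage (0/1/2, NaN missing).  Monomorphic
    sites (no variance among nonmissing calls) are dropped; missing values
    are imputed to the site mean.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.size == 0:
        return dosage.T
    means = np.nanmean(dosage, axis=1)
    with np.errstate(invalid="ignore"):
        variable = np.nanstd(dosage, axis=1) > 0
    dosage = dosage[variable]
    means = means[variable]
    filled = np.where(np.isnan(dosage), means[:, None], dosage)
    return filled.T


def _renumber_by_size(raw_labels: np.ndarray, k: int) -> np.ndarray:
    """Map raw k-means labels to 1..k ordered by decreasing cluster size
    (ties: lower raw label first)."""
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    mapping = np.empty(k, dtype=int)
    mapping[order] = np.arange(1, k + 1)
    return mapping[raw_labels]


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_restarts: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    # k-means can in principle converge with an empty cluster; retry with
    # fresh initializations before giving up.
    for retry in range(1, 6):
        if len(np.unique(labels)) == k:
            return labels
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + retry)
        labels = km.fit_predict(X)
    if len(np.unique(labels)) != k:
        raise RuntimeError(f"k-means failed to fill all {k} clusters")
    return labels


def silhouette_scan(
    X: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> tuple[dict[int, float], int]:
    """Average silhouette width for each candidate k; chosen_k is the argmax.

    Ties break toward the smaller k.  Raises on a degenerate matrix whose
    rows are all identical (no structure to score).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate matrix: all samples identical")
    widths: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= X.shape[0] - 1:
            raise ValueError(f"k={k} outside [2, n_samples-1]")
        labels = _fit_kmeans(X, k, seed, n_restarts)
        widths[k] = float(silhouette_score(X, labels))
    chosen = min(widths, key=lambda k: (-widths[k], k))
    return widths, chosen


def assign_clusters(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> ClusterAssignment:
    """k-means labels renumbered by decreasing cluster size, 1..k."""
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of samples")
    if k == X.shape[0]:
        labels = np.arange(1, k + 1)
    else:
        labels = _renumber_by_size(_fit_kmeans(X, k, seed, n_restarts), k)
    ids = sample_ids or [f"S{i:04d}" for i in range(X.shape[0])]
    return ClusterAssignment(sample_ids=list(ids), labels=labels, k=k)


def pca_coords(X: np.ndarray, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA: per-sample coordinates and variance fractions."""
    X = np.asarray(X, dtype=float)
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_
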