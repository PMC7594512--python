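"""Perturbation-stability clustering with AUC-based selection of the cluster
number, and connectivity-fusion integration of several omics matrices.

For a candidate cluster number k the original data are partitioned once and
n_perturb Gaussian-noise-perturbed copies are each partitioned again. The
binary sample x sample connectivity matrix of the original partition is
compared with the mean connectivity over the perturbed partitions: the
entrywise discrepancies D in [0, 1] over off-diagonal pairs are summarized by
the area under their empirical CDF on [0, 1], which equals 1 - mean(D). A
perfectly stable k (every perturbed partition identical to the original)
scores AUC = 1; the k with the highest AUC is selected, ties broken towards
the smallest k.

Integration averages the per-omics perturbed connectivity matrices into one
fused similarity S_k, partitions 1 - S_k with hierarchical clustering, and
scores each k by the same discrepancy AUC against S_k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

Method = Literal["kmeans", "hclust"]

DEFAULT_N_PERTURB = 50
DEFAULT_NOISE_SCALE = 1.0
DEFAULT_KMEANS_RESTARTS = 20
DEFAULT_LINKAGE = "average"

#: Diagnostic threshold below which no k is considered strongly supported.
STRONG_STRUCTURE_AUC = 0.9


@dataclass
class ConnectivityMatrix:
    """Symmetric sample x sample co-clustering matrix with unit diagonal, entries in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("connectivity matrix shape does not match sample ids")
        self.values = v


@dataclass
class KSelectionTrace:
    """Stability AUC per candidate k and the selected k_star (argmax, smallest on ties)."""

    k_values: list[int]
    auc: list[float]

    @property
    def k_star(self) -> int:
        return self.k_values[int(np.argmax(self.auc))]

    @property
    def has_strong_structure(self) -> bool:
        return max(self.auc) >= STRONG_STRUCTURE_AUC

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "auc": self.auc})


@dataclass
class ClusteringResult:
    """Final partition: per-sample labels at k_star plus the selection trace."""

    labels: np.ndarray
    k_star: int
    trace: KSelectionTrace
    connectivity: ConnectivityMatrix

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.connectivity.sample_ids, "subgroup": self.labels + 1}
        )


def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def base_cluster(
    data: np.ndarray,
    k: int,
    method: Method = "kmeans",
    seed: int | None = None,
    n_restarts: int = DEFAULT_KMEANS_RESTARTS,
    linkage_method: str = DEFAULT_LINKAGE,
    distance: np.ndarray | None = None,
) -> np.ndarray:
    """Partition samples (rows) into exactly k groups.

    ``kmeans`` runs seeded multi-restart k-means; ``hclust`` cuts an
    agglomerative tree built from Euclidean distances (or a supplied square
    distance matrix) at k. Labels are integers 0..k-1.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0] if distance is None else distance.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if method == "kmeans":
        if distance is not None:
            raise ValueError("precomputed distances are only supported with hclust")
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        return km.fit_predict(data)
    if method == "hclust":
        if distance is None:
            condensed = pdist(data, metric="euclidean")
        else:
            condensed = squareform(np.asarray(distance, dtype=float), checks=False)
        tree = linkage(condensed, method=linkage_method)
        labels = fcluster(tree, t=k, criterion="maxclust") - 1
        return labels.astype(int)
    raise ValueError(f"unknown method {method!r}")


def connectivity_from_labels(labels: Sequence) -> np.ndarray:
    """Binary co-membership matrix: entry (i, j) = 1 iff labels[i] == labels[j]."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("empty label vector")
    return (lab[:, None] == lab[None, :]).astype(float)


def perturb(data: np.ndarray, noise_scale: float, seed: int | None = None) -> np.ndarray:
    """Add i.i.d. Gaussian noise with sd = noise_scale x median per-feature sd."""
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    sd = float(np.median(data.std(axis=0, ddof=0)))
    if sd == 0.0:
        sd = 1.0  # degenerate constant data: unit noise keeps the scheme defined
    return data + rng.normal(0.0, noise_scale * sd, size=data.shape)


def _perturbed_connectivity(
    data: np.ndarray,
    k: int,
    method: Method,
    n_perturb: int,
    noise_scale: float,
    seed: int | None,
    n_restarts: int,
    linkage_method: str,
) -> np.ndarray:
    """Mean binary connectivity over n_perturb noise-perturbed partitions.

    A perturbed copy that yields fewer than k nonempty clusters is resampled,
    at most 3 extra attempts, then accepted as-is.
    """
    if n_perturb < 2:
        raise ValueError("n_perturb must be >= 2")
    seeds = _child_seeds(seed, 2 * n_perturb + n_perturb * 4)
    acc = np.zeros((data.shape[0], data.shape[0]))
    pos = 0
    for _ in range(n_perturb):
        for _attempt in range(4):
            noisy = perturb(data, noise_scale, seed=seeds[pos])
            labels = base_cluster(
                noisy, k, method=method, seed=seeds[pos + 1],
                n_restarts=n_restarts, linkage_method=linkage_method,
            )
            pos += 2
            if len(np.unique(labels)) == k:
                break
        acc += connectivity_from_labels(labels)
    return acc / n_perturb


def _discrepancy_auc(reference: np.ndarray, averaged: np.ndarray) -> float:
    """Area under the empirical CDF of |reference - averaged| off-diagonal entries.

    Both matrices have entries in [0, 1], so the AUC over [0, 1] equals
    1 - mean discrepancy; D identically zero gives exactly 1.
    """
    n = reference.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = np.abs(reference - averaged)[off]
    return float(1.0 - d.mean())


def stability_auc(
    data: np.ndarray,
    k: int,
    method: Method = "kmeans",
    n_perturb: int = DEFAULT_N_PERTURB,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int | None = None,
    n_restarts: int = DEFAULT_KMEANS_RESTARTS,
    linkage_method: str = DEFAULT_LINKAGE,
) -> float:
    """Perturbation-stability AUC of clustering ``data`` at ``k``."""
    seeds = _child_seeds(seed, 2)
    labels0 = base_cluster(
        data, k, method=method, seed=seeds[0], n_restarts=n_restarts, linkage_method=linkage_method
    )
    c0 = connectivity_from_labels(labels0)
    avg = _perturbed_connectivity(
        data, k, method, n_perturb, noise_scale, seeds[1], n_restarts, linkage_method
    )
    return _discrepancy_auc(c0, avg)


def select_k(
    data: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    method: Method = "kmeans",
    n_perturb: int = DEFAULT_N_PERTURB,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int | None = None,
    n_restarts: int = DEFAULT_KMEANS_RESTARTS,
    linkage_method: str = DEFAULT_LINKAGE,
) -> KSelectionTrace:
    """Stability AUC for every candidate k; k_star is the (smallest) argmax."""
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > data.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    seeds = _child_seeds(seed, len(ks))
    aucs = [
        stability_auc(
            data, k, method=method, n_perturb=n_perturb, noise_scale=noise_scale,
            seed=s, n_restarts=n_restarts, linkage_method=linkage_method,
        )
        for k, s in zip(ks, seeds)
    ]
    return KSelectionTrace(k_values=ks, auc=aucs)


def single_subtype(
    data: np.ndarray,
    sample_ids: Sequence[str],
    k_range: Sequence[int] = range(2, 11),
    method: Method = "kmeans",
    n_perturb: int = DEFAULT_N_PERTURB,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int | None = None,
    n_restarts: int = DEFAULT_KMEANS_RESTARTS,
    linkage_method: str = DEFAULT_LINKAGE,
) -> ClusteringResult:
    """Single-omics subtyping: pick k by stability AUC and partition at k_star."""
    trace = select_k(
        data, k_range, method=method, n_perturb=n_perturb, noise_scale=noise_scale,
        seed=seed, n_restarts=n_restarts, linkage_method=linkage_method,
    )
    seeds = _child_seeds(seed, 2)
    labels = base_cluster(
        data, trace.k_star, method=method, seed=seeds[0],
        n_restarts=n_restarts, linkage_method=linkage_method,
    )
    avg = _perturbed_connectivity(
        data, trace.k_star, method, n_perturb, noise_scale, seeds[1], n_restarts, linkage_method
    )
    return ClusteringResult(
        labels=labels,
        k_star=trace.k_star,
        trace=trace,
        connectivity=ConnectivityMatrix(list(sample_ids), avg),
    )


def integrate_subtype(
    omics: Sequence[np.ndarray],
    sample_ids: Sequence[str],
    k_range: Sequence[int] = range(2, 11),
    n_perturb: int = DEFAULT_N_PERTURB,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int | None = None,
    n_restarts: int = DEFAULT_KMEANS_RESTARTS,
    linkage_method: str = DEFAULT_LINKAGE,
    base_method: Method = "kmeans",
) -> ClusteringResult:
    """Connectivity-fusion integration of >= 2 sample-aligned omics matrices.

    Per omics and per k the perturbation-averaged connectivity is computed
    (k-means base partitions); the unweighted entrywise mean over omics gives
    the fused similarity S_k, whose complement is partitioned hierarchically
    at k. Each k is scored by the discrepancy AUC between that partition's
    connectivity and S_k; labels at the winning k are returned.
    """
    if len(omics) < 2:
        raise ValueError("integration needs at least 2 omics matrices")
    n = len(sample_ids)
    for o in omics:
        if o.shape[0] != n:
            raise ValueError("omics matrices are not sample-aligned")
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError("k_range must lie within [2, n_samples - 1]")
    seeds = _child_seeds(seed, len(ks) * len(omics))
    aucs: list[float] = []
    labels_per_k: list[np.ndarray] = []
    fused_per_k: list[np.ndarray] = []
    pos = 0
    for k in ks:
        parts = []
        for o in omics:
            parts.append(
                _perturbed_connectivity(
                    o, k, base_method, n_perturb, noise_scale, seeds[pos], n_restarts, linkage_method
                )
            )
            pos += 1
        fused = np.mean(parts, axis=0)
        fused = (fused + fused.T) / 2.0
        np.fill_diagonal(fused, 1.0)
        labels = base_cluster(
            np.empty((n, 0)), k, method="hclust", distance=1.0 - fused,
            linkage_method=linkage_method,
        )
        aucs.append(_discrepancy_auc(connectivity_from_labels(labels), fused))
        labels_per_k.append(labels)
        fused_per_k.append(fused)
    trace = KSelectionTrace(k_values=ks, auc=aucs)
    best = int(np.argmax(aucs))
    return ClusteringResult(
        labels=labels_per_k[best],
        k_star=ks[best],
        trace=trace,
        connectivity=ConnectivityMatrix(list(sample_ids), fused_per_k[best]),
    )


def overlap_chi2(labels_a: Sequence, labels_b: Sequence) -> tuple[float, float]:
    """Pearson chi-square test of independence between two labelings of the same samples."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings cover different sample sets")
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table: a labeling has a single class")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
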