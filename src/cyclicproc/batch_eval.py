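"""Batch-effect evaluation: kBET, stratified sampling, clustering, and
replicate cluster-composition correlation.

kBET scores batch mixing on a k-nearest-neighbor graph: for randomly chosen
cells, the batch-label counts in the neighborhood (the cell plus its k
neighbors) are compared to the global batch proportions with a Pearson
chi-squared test; the rejection rate — the fraction of neighborhoods whose
test rejects at level alpha — is 0 for perfectly mixed batches and 1 when
batches do not mix at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NeighborGraph:
    """Exact k-nearest-neighbor lists (feature-space Euclidean distance).

    ``indices[i]`` holds the ids of cell i's k nearest neighbors, nearest
    first; a cell is never its own neighbor; distance ties are broken by the
    smaller cell index (deterministic).
    """

    indices: np.ndarray  # (n, k) int
    k: int

    def __post_init__(self) -> None:
        n = self.indices.shape[0]
        if self.indices.shape[1] != self.k:
            raise ValueError("indices width differs from k")
        if np.any(self.indices == np.arange(n)[:, None]):
            raise ValueError("a cell lists itself as neighbor")
        if self.indices.min() < 0 or self.indices.max() >= n:
            raise ValueError("neighbor id out of range")


@dataclass(frozen=True)
class KbetResult:
    rejection_rate: float
    alpha: float
    k: int
    n_subsets: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rejection_rate <= 1.0:
            raise ValueError("rejection rate must lie in [0, 1]")


def build_knn(features: np.ndarray, k: int, chunk: int = 1024) -> NeighborGraph:
    """Exact k-NN by Euclidean distance, ties broken by cell index."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    indices = np.empty((n, k), dtype=np.int64)
    sq = (x**2).sum(axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2.0 * (x[start:stop] @ x.T) + sq[None, :]
        np.maximum(d2, 0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        ids = np.arange(n)
        for i in range(stop - start):
            # sort by (distance, index): distance ties go to the smaller id
            order = np.lexsort((ids, d2[i]))
            indices[start + i] = order[:k]
    return NeighborGraph(indices=indices, k=k)


def default_k(batch_labels: np.ndarray) -> int:
    """kBET heuristic: a quarter of the mean batch size, capped at n−1."""
    labels = np.asarray(batch_labels)
    _, counts = np.unique(labels, return_counts=True)
    k = int(np.floor(counts.mean() / 4.0))
    return max(1, min(k, len(labels) - 1))


def kbet_rejection_rate(graph: NeighborGraph, batch_labels: np.ndarray,
                        alpha: float = 0.05, n_subsets: int = 100,
                        seed: int = 0) -> KbetResult:
    """kBET rejection rate over random neighborhoods.

    Each tested neighborhood is an anchor cell plus its k neighbors (k+1
    cells); observed batch counts are compared to expected counts (global
    batch proportions × (k+1)) by a Pearson chi-squared statistic with
    B−1 degrees of freedom, without continuity correction.
    """
    labels = np.asarray(batch_labels)
    n = len(labels)
    if graph.indices.shape[0] != n:
        raise ValueError("graph and batch labels disagree on cell count")
    uniq, inv = np.unique(labels, return_inverse=True)
    n_batches = len(uniq)
    if n_batches < 2:
        raise ValueError("kBET needs at least 2 batches")
    if graph.k < 10:
        warnings.warn(f"k={graph.k} < 10; kBET is unstable", stacklevel=2)

    global_prop = np.bincount(inv, minlength=n_batches) / n
    expected = global_prop * (graph.k + 1)

    rng = np.random.default_rng(seed)
    anchors = rng.choice(n, size=min(n_subsets, n), replace=False)
    df = n_batches - 1
    rejected = 0
    for a in anchors:
        members = np.concatenate(([a], graph.indices[a]))
        observed = np.bincount(inv[members], minlength=n_batches)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        p = stats.chi2.sf(chi2, df)
        if p < alpha:
            rejected += 1
    return KbetResult(rejection_rate=rejected / len(anchors), alpha=alpha,
                      k=graph.k, n_subsets=len(anchors), seed=seed)


def stratified_sample(table: pd.DataFrame, n_per_group: int = 600,
                      group_keys: tuple[str, ...] = ("core_id", "batch_id"),
                      seed: int = 0) -> pd.DataFrame:
    """Sample exactly ``n_per_group`` cells per group, without replacement.

    Mirrors the evaluation design of sampling 600 cells per TMA core from
    each batch.  Groups smaller than ``n_per_group`` raise an error naming
    the deficient groups.
    """
    deficient = []
    for key, grp in table.groupby(list(group_keys), sort=True):
        if len(grp) < n_per_group:
            deficient.append((key, len(grp)))
    if deficient:
        raise ValueError(
            f"groups with fewer than {n_per_group} cells: {deficient}")
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in table.groupby(list(group_keys), sort=True):
        take = rng.choice(len(grp), size=n_per_group, replace=False)
        parts.append(grp.iloc[np.sort(take)])
    return pd.concat(parts, axis=0)


def cluster_cells(features: np.ndarray, resolution: float = 0.6,
                  k: int = 15, seed: int = 0) -> np.ndarray:
    """Graph-based Leiden clustering of the cell × feature matrix.

    Builds the exact k-NN graph and partitions it with the Leiden algorithm
    (RB-configuration quality with the given resolution).  Cluster ids are
    0-based and contiguous; a fixed seed makes the result deterministic.
    """
    try:
        import igraph
        import leidenalg
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("Leiden backend (python-igraph + leidenalg) "
                           "unavailable") from exc
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if n == 2 or np.allclose(x, x[0]):
        return np.zeros(n, dtype=int)
    k = min(k, n - 1)
    graph = build_knn(x, k)
    edges = {(min(i, int(j)), max(i, int(j)))
             for i in range(n) for j in graph.indices[i]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    labels = np.asarray(part.membership, dtype=int)
    # relabel to 0-based contiguous in order of first appearance
    _, contiguous = np.unique(labels, return_inverse=True)
    return contiguous


def cluster_composition_correlation(cluster_labels: np.ndarray,
                                    replicate_ids: np.ndarray,
                                    unit_ids: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of cluster composition between replicates.

    For every unit (e.g. TMA core) and replicate (e.g. section), the vector
    of per-cluster cell fractions (summing to 1) is formed on the shared
    cluster label space; the Pearson r of these vectors is computed for each
    replicate pair within each unit.

    Returns a DataFrame with columns unit, replicate_a, replicate_b, r.
    """
    labels = np.asarray(cluster_labels)
    reps = np.asarray(replicate_ids)
    units = np.asarray(unit_ids)
    if not (len(labels) == len(reps) == len(units)):
        raise ValueError("input arrays differ in length")
    all_clusters = np.unique(labels)
    rep_list = sorted(np.unique(reps).tolist())
    if len(rep_list) < 2:
        raise ValueError("need at least 2 replicates")

    rows = []
    for unit in sorted(np.unique(units).tolist()):
        comps = {}
        for rep in rep_list:
            sel = (units == unit) & (reps == rep)
            if not sel.any():
                raise ValueError(f"unit {unit!r} absent from replicate {rep!r}")
            counts = np.array([(labels[sel] == c).sum() for c in all_clusters],
                              dtype=float)
            comps[rep] = counts / counts.sum()
        for i, ra in enumerate(rep_list):
            for rb in rep_list[i + 1:]:
                r = float(stats.pearsonr(comps[ra], comps[rb])[0])
                rows.append({"unit": unit, "replicate_a": ra,
                             "replicate_b": rb, "r": r})
    return pd.DataFrame(rows)
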