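"""Community structure: JSD/Ward clustering, validation statistics, diversity.

Community profiles are clustered by pairwise Jensen–Shannon divergence (natural
log, used directly as the distance, no square root) under the Ward.D2 linkage
criterion — the combination conventionally used to derive vaginal community
state types from compositional data.  Internal validation statistics
(connectivity, mean silhouette width, Dunn index) support the choice of cluster
count but never make it automatically: the cluster count is a user decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import jensenshannon, pdist, squareform
from scipy.stats import entropy
from sklearn.metrics import silhouette_score

from .tables import AbundanceTable, TableError

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterValidation",
    "jensen_shannon_divergence",
    "jsd_distance_matrix",
    "ward_hierarchical_clustering",
    "cut_clusters",
    "validate_clustering",
    "alpha_diversity",
    "cross_tabulate_clusterings",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample × sample distance matrix with zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric within 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if (v < 0).any():
            raise ValueError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence in scipy linkage-matrix form.

    ``merges`` is an (n−1) × 4 array: merged node indices, merge height, and
    merged-cluster size; leaves are 0..n−1, internal nodes n..2n−2.
    """

    merges: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges, got {self.merges.shape}")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        order = sch.leaves_list(self.merges)
        return [self.sample_ids[i] for i in order]


@dataclass(frozen=True)
class ClusterValidation:
    """Internal validation statistics for one cluster count."""

    k: int
    connectivity: float  # lower is better
    silhouette: float    # higher is better, in [-1, 1]
    dunn: float          # higher is better


def _check_probability(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} sums to {p.sum()!r}, not 1 within {_NORM_TOL}")
    return p


def jensen_shannon_divergence(p: Iterable[float], q: Iterable[float]) -> float:
    """JSD(p, q) = ½KL(p‖m) + ½KL(q‖m) with m = (p+q)/2, natural log.

    Symmetric, zero iff p = q, bounded above by ln 2 (attained on disjoint
    supports).  Zero probabilities contribute nothing (0·log(0/·) := 0).
    """
    p = _check_probability(np.asarray(list(p)), "p")
    q = _check_probability(np.asarray(list(q)), "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    # scipy returns the JS *distance* sqrt(JSD); square to recover divergence
    return float(jensenshannon(p, q) ** 2)


def jsd_distance_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise JSD between sample rows of a relative abundance table."""
    if table.scale != "relative":
        raise TableError("JSD requires a relative abundance table")
    d = pdist(table.values, metric="jensenshannon") ** 2
    full = squareform(d)
    np.fill_diagonal(full, 0.0)
    return DistanceMatrix(tuple(table.sample_ids), full)


def ward_hierarchical_clustering(distances: DistanceMatrix) -> Dendrogram:
    """Agglomerate under the Ward.D2 criterion on the supplied distances.

    The squared-distance Lance–Williams update is applied to the distances as
    given (they are not squared beforehand), matching ``hclust(method =
    "ward.D2")`` on a JSD distance object.  Deterministic for a given input.
    """
    if distances.n < 2:
        raise ValueError("clustering requires at least 2 samples")
    merges = sch.linkage(distances.condensed(), method="ward")
    return Dendrogram(merges, distances.sample_ids)


def cut_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the merge sequence into exactly ``k`` clusters.

    Returns integer labels 1..k indexed by sample id, renumbered in order of
    first appearance.
    """
    n = len(dendrogram.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = sch.fcluster(dendrogram.merges, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(
            f"could not obtain exactly {k} clusters (tied merge heights)"
        )
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return pd.Series(labels, index=list(dendrogram.sample_ids), name="cluster")


def _connectivity(values: np.ndarray, labels: np.ndarray, neighbors: int) -> float:
    """Sum over samples of 1/j for each j-th nearest neighbor not co-clustered.

    Neighbor ranking ties are broken by sample order (stable argsort).
    """
    n = len(labels)
    total = 0.0
    for i in range(n):
        order = np.argsort(values[i], kind="stable")
        order = order[order != i][:neighbors]
        for j, idx in enumerate(order, start=1):
            if labels[idx] != labels[i]:
                total += 1.0 / j
    return total


def _dunn(values: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min between-cluster distance / max within-cluster diameter."""
    uniq = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for a in uniq:
        ia = np.flatnonzero(labels == a)
        if len(ia) > 1:
            max_within = max(max_within, values[np.ix_(ia, ia)].max())
        for b in uniq:
            if b <= a:
                continue
            ib = np.flatnonzero(labels == b)
            min_between = min(min_between, values[np.ix_(ia, ib)].min())
    if max_within == 0.0:
        return np.inf
    return float(min_between / max_within)


def validate_clustering(
    distances: DistanceMatrix,
    dendrogram: Dendrogram,
    k_range: Sequence[int],
    neighbors: int = 10,
) -> list[ClusterValidation]:
    """Connectivity, mean silhouette width, and Dunn index per cluster count.

    ``neighbors`` is the neighborhood size for connectivity (default 10, the
    convention of the standard internal-validation package).  The optimum per
    statistic is min connectivity, max silhouette, max Dunn — reported to, not
    decided for, the user.
    """
    if neighbors >= distances.n:
        raise ValueError(
            f"neighbors ({neighbors}) must be < number of samples ({distances.n})"
        )
    out = []
    for k in k_range:
        labels = cut_clusters(dendrogram, k).to_numpy()
        sil = float(
            silhouette_score(distances.values, labels, metric="precomputed")
        ) if 1 < k < distances.n else float("nan")
        out.append(
            ClusterValidation(
                k=int(k),
                connectivity=_connectivity(distances.values, labels, neighbors),
                silhouette=sil,
                dunn=_dunn(distances.values, labels),
            )
        )
    return out


_ALPHA_METRICS = ("observed", "shannon", "simpson", "invsimpson")


def alpha_diversity(
    table: AbundanceTable, metrics: Sequence[str] = _ALPHA_METRICS
) -> pd.DataFrame:
    """Per-sample alpha diversity, tidy: sample_id, metric, value.

    observed — number of features with abundance > 0; shannon — −Σ p ln p;
    simpson — 1 − Σ p²; invsimpson — 1 / Σ p².  Counts are converted to
    proportions internally for the evenness metrics.
    """
    unknown = set(metrics) - set(_ALPHA_METRICS)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    values = table.values
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        raise TableError("alpha diversity undefined for all-zero samples")
    props = values / sums[:, None]
    rows = []
    for name in metrics:
        if name == "observed":
            vals = (values > 0).sum(axis=1).astype(float)
        elif name == "shannon":
            vals = np.array([entropy(p) for p in props])
        elif name == "simpson":
            vals = 1.0 - (props**2).sum(axis=1)
        else:  # invsimpson
            vals = 1.0 / (props**2).sum(axis=1)
        rows.append(
            pd.DataFrame(
                {"sample_id": table.sample_ids, "metric": name, "value": vals}
            )
        )
    return pd.concat(rows, ignore_index=True)


def cross_tabulate_clusterings(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    """Contingency table of two clusterings of the same samples."""
    if set(a.index) != set(b.index):
        raise ValueError("clusterings cover different sample sets")
    b = b.reindex(a.index)
    return pd.crosstab(a, b)
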