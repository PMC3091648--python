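"""Fuzzy clustering by local approximation of membership (FLAME).

The algorithm seeds one cluster per cluster-supporting object (CSO, a
local density maximum over its k nearest neighbours), fixes CSOs and
outliers as indicator rows, and iteratively replaces every remaining
gene's membership vector by the weighted average of its neighbours'
vectors until the fixed point.  Genes whose converged membership exceeds
a cutoff in more than one cluster belong to all of them, which is the
point: context-dependent co-expression is kept, not averaged away.

Distances default to 1 - Pearson correlation between expression
profiles, neighbour weights are proportional to the neighbour's density,
and the classic parameterisation is k = 7 neighbours, at most 500
approximation steps and a 35% membership cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "KnnGraph",
    "build_knn_graph",
    "estimate_density",
    "classify_objects",
    "propagate_memberships",
    "solve_membership_fixed_point",
    "extract_clusters",
    "FlameClustering",
]

_EPS = 1e-12

CSO = "CSO"
OUTLIER = "outlier"
REST = "rest"


@dataclass
class KnnGraph:
    """k-nearest-neighbour structure of the gene profiles.

    ``indices[i]`` are the k neighbours of gene i (ties broken by row
    order), ``distances`` the matching distances, ``densities`` the
    per-gene density 1 / mean kNN distance, and ``weights[i]`` the
    density-proportional neighbour weights, positive and summing to 1.
    """

    ids: list[str]
    indices: np.ndarray
    distances: np.ndarray
    densities: np.ndarray
    weights: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def _distance_matrix(profiles: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        # 1 - Pearson r; constant profiles have undefined correlation and
        # are treated as maximally dissimilar to everything else.
        with np.errstate(invalid="ignore", divide="ignore"):
            d = squareform(pdist(profiles, metric="correlation"))
        d = np.nan_to_num(d, nan=2.0)
        np.fill_diagonal(d, 0.0)
        return d
    return squareform(pdist(profiles, metric=metric))


def build_knn_graph(
    profiles: np.ndarray | pd.DataFrame, k: int = 7, metric: str = "correlation"
) -> KnnGraph:
    """Build the kNN graph over gene expression profiles.

    Each gene gets exactly ``k`` neighbours (nearest by the chosen
    metric, ties broken by row order) with density-proportional weights.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = [str(i) for i in profiles.index]
        x = profiles.to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
        ids = [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} genes, got {n}")
    if not np.isfinite(x).all():
        raise ValueError("profiles must be finite")
    d = _distance_matrix(x, metric)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    knn_dist = np.take_along_axis(d, order, axis=1)
    densities = 1.0 / (knn_dist.mean(axis=1) + _EPS)
    weights = densities[order]
    weights = weights / weights.sum(axis=1, keepdims=True)
    return KnnGraph(ids=ids, indices=order, distances=knn_dist, densities=densities, weights=weights)


def estimate_density(graph: KnnGraph) -> np.ndarray:
    """Per-gene density: reciprocal of the mean kNN distance."""
    return 1.0 / (graph.distances.mean(axis=1) + _EPS)


def classify_objects(graph: KnnGraph, outlier_factor: float = 2.0) -> np.ndarray:
    """Label every gene CSO, outlier, or rest.

    A gene is a CSO when its density strictly exceeds every neighbour's
    (density ties broken towards the lexicographically smallest gene
    identifier); an outlier when its density lies below
    mean - ``outlier_factor`` * SD of all densities and below all its
    neighbours'.
    """
    dens = graph.densities
    id_rank = np.argsort(np.argsort(np.asarray(graph.ids, dtype=object), kind="stable"))
    labels = np.full(graph.n, REST, dtype=object)
    threshold = dens.mean() - outlier_factor * dens.std()
    for i in range(graph.n):
        nbrs = graph.indices[i]
        beats = [
            dens[i] > dens[j] or (dens[i] == dens[j] and id_rank[i] < id_rank[j]) for j in nbrs
        ]
        if all(beats):
            labels[i] = CSO
        elif dens[i] < threshold and all(dens[i] < dens[j] for j in nbrs):
            labels[i] = OUTLIER
    return labels


def propagate_memberships(
    graph: KnnGraph,
    object_class: np.ndarray,
    max_iterations: int = 500,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, int, bool]:
    """Iterate the local membership approximation to its fixed point.

    Returns the membership matrix (genes x [cluster per CSO + outlier
    group]), the number of iterations and a convergence flag.  CSO and
    outlier rows are fixed indicator vectors; each remaining row is
    repeatedly replaced by the weighted average of its neighbours' rows,
    so every row stays a convex combination (sums to 1 throughout).
    """
    cso_idx = np.flatnonzero(object_class == CSO)
    if len(cso_idx) == 0:
        raise ValueError("no cluster-supporting object found; cannot seed clusters")
    order = np.argsort([graph.ids[i] for i in cso_idx], kind="stable")
    cso_idx = cso_idx[order]
    columns = [f"C{j + 1}" for j in range(len(cso_idx))] + [OUTLIER]
    n_cols = len(columns)

    m = np.full((graph.n, n_cols), 1.0 / n_cols)
    fixed = np.zeros(graph.n, dtype=bool)
    for col, i in enumerate(cso_idx):
        m[i] = 0.0
        m[i, col] = 1.0
        fixed[i] = True
    for i in np.flatnonzero(object_class == OUTLIER):
        m[i] = 0.0
        m[i, -1] = 1.0
        fixed[i] = True

    free = np.flatnonzero(~fixed)
    converged = len(free) == 0
    it = 0
    for it in range(1, max_iterations + 1):
        if converged:
            break
        updated = np.einsum("ik,ikc->ic", graph.weights[free], m[graph.indices[free]])
        delta = np.abs(updated - m[free]).max() if len(free) else 0.0
        m[free] = updated
        if delta < tol:
            converged = True
    return pd.DataFrame(m, index=graph.ids, columns=columns), it, converged


def solve_membership_fixed_point(
    graph: KnnGraph, object_class: np.ndarray
) -> pd.DataFrame:
    """Exact fixed point of the propagation as a linear system.

    For the free rows R the fixed point satisfies
    ``M_R = W_RR M_R + W_RF M_F`` with F the fixed (CSO/outlier) rows;
    solving ``(I - W_RR) M_R = W_RF M_F`` directly gives the limit the
    iteration approaches.  Used as an independent cross-check.
    """
    memberships, _, _ = propagate_memberships(graph, object_class, max_iterations=0)
    m = memberships.to_numpy()
    fixed = np.zeros(graph.n, dtype=bool)
    for i in range(graph.n):
        if object_class[i] in (CSO, OUTLIER):
            fixed[i] = True
    free = np.flatnonzero(~fixed)
    if len(free) == 0:
        return memberships
    w_full = np.zeros((graph.n, graph.n))
    for i in range(graph.n):
        w_full[i, graph.indices[i]] = graph.weights[i]
    a = np.eye(len(free)) - w_full[np.ix_(free, free)]
    b = w_full[free][:, fixed] @ m[fixed]
    m[free] = np.linalg.solve(a, b)
    out = memberships.copy()
    out.iloc[:, :] = m
    return out


def extract_clusters(memberships: pd.DataFrame, cutoff: float = 0.35) -> dict[str, set[str]]:
    """Assign genes to every cluster where membership >= ``cutoff``.

    The outlier group is excluded; with the default 35% cutoff a gene can
    belong to at most two clusters.
    """
    clusters: dict[str, set[str]] = {}
    for col in memberships.columns:
        if col == OUTLIER:
            continue
        members = set(memberships.index[memberships[col] >= cutoff])
        if members:
            clusters[col] = members
    return clusters


class FlameClustering(ClusterMixin, BaseEstimator):
    """FLAME fuzzy clustering as a scikit-learn style estimator.

    Parameters
    ----------
    n_neighbors:
        Neighbourhood size k of the kNN graph.
    max_iter:
        Maximum membership approximation steps.
    tol:
        Convergence tolerance on the max absolute row change.
    membership_cutoff:
        Minimum membership for cluster assignment (genes may pass it in
        more than one cluster).
    metric:
        ``"correlation"`` (1 - Pearson r, the co-expression default) or
        any :func:`scipy.spatial.distance.pdist` metric.
    outlier_factor:
        Densities below mean - ``outlier_factor`` * SD mark outliers.

    Attributes
    ----------
    memberships_ : pandas.DataFrame
        Row-stochastic gene x cluster memberships (last column: outliers).
    labels_ : numpy.ndarray
        Hard labels by maximum membership; -1 for the outlier group.
    object_class_ : numpy.ndarray
        Per-gene ``"CSO"`` / ``"outlier"`` / ``"rest"``.
    clusters_ : dict
        Cluster id -> set of gene ids at the membership cutoff.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_neighbors: int = 7,
        max_iter: int = 500,
        tol: float = 1e-6,
        membership_cutoff: float = 0.35,
        metric: str = "correlation",
        outlier_factor: float = 2.0,
    ):
        self.n_neighbors = n_neighbors
        self.max_iter = max_iter
        self.tol = tol
        self.membership_cutoff = membership_cutoff
        self.metric = metric
        self.outlier_factor = outlier_factor

    def fit(self, X, y=None):
        graph = build_knn_graph(X, k=self.n_neighbors, metric=self.metric)
        self.graph_ = graph
        self.object_class_ = classify_objects(graph, outlier_factor=self.outlier_factor)
        self.memberships_, self.n_iter_, self.converged_ = propagate_memberships(
            graph, self.object_class_, max_iterations=self.max_iter, tol=self.tol
        )
        self.clusters_ = extract_clusters(self.memberships_, cutoff=self.membership_cutoff)
        hard = self.memberships_.to_numpy().argmax(axis=1)
        n_clusters = self.memberships_.shape[1] - 1
        self.labels_ = np.where(hard == n_clusters, -1, hard)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
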