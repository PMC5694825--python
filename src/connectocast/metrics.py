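"""Connectome graph metrics: binarization, nodal metrics, modules and hubs.

A subject's functional connectome arrives as a symmetric region-by-region
weighted correlation matrix. The analysis chain binarizes each matrix at its
*minimum connection density* — the lowest edge density at which the network
is fully connected, admitting edges in descending absolute weight — and then
computes per-region graph metrics on the binary network:

* degree ``k_i`` — number of connections,
* clustering coefficient ``C_i`` — fraction of neighbor pairs that are
  themselves connected, ``2 t_i / (k_i (k_i - 1))``,
* betweenness centrality ``B_i`` — unnormalized shortest-path load,
* participation coefficient ``P_i = 1 - sum_s (k_is / k_i)^2`` over modules
  ``s`` of a partition,
* modularity ``Q`` of the partition.

Hubs are regions whose degree, betweenness or clustering exceed the network
mean by more than one standard deviation; hubs are *connector* type when
``P_i`` exceeds 0.30 and *provincial* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedConnectivityMatrix",
    "BinaryNetwork",
    "ModulePartition",
    "minimum_density_edge_count",
    "binarize_at_edge_count",
    "binarize_to_min_density",
    "binarize_cohort",
    "degree",
    "clustering_coefficient",
    "betweenness_centrality",
    "detect_modules",
    "modularity",
    "participation_coefficient",
    "node_metric_table",
    "group_mean_network",
    "classify_hubs",
    "CONNECTOR_PARTICIPATION_THRESHOLD",
]

#: Participation-coefficient cutoff separating connector from provincial hubs,
#: following the Guimera–Amaral cartographic taxonomy.
CONNECTOR_PARTICIPATION_THRESHOLD = 0.30

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class WeightedConnectivityMatrix:
    """Symmetric region x region functional-correlation matrix for one subject."""

    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(w, w.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("connectivity matrix must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BinaryNetwork:
    """Thresholded 0/1 network with its realized edge density."""

    labels: list[str]
    adjacency: np.ndarray
    density: float

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.labels)))


@dataclass(frozen=True)
class ModulePartition:
    """Non-overlapping assignment of regions to modules with its Q score."""

    labels: list[str]
    module_of: np.ndarray  # int module id per region, aligned with labels
    modularity: float

    @property
    def n_modules(self) -> int:
        return int(self.module_of.max()) + 1 if self.module_of.size else 0


def _ranked_edges(weights: np.ndarray) -> list[tuple[int, int]]:
    """Non-zero upper-triangle edges sorted by descending |weight|.

    Ties broken by (lower row index, lower column index) so the admission
    order is fully deterministic.
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = np.abs(weights[iu, ju])
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))
    return list(zip(iu[order].tolist(), ju[order].tolist()))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.n_components = n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb
            self.n_components -= 1


def _complete_ties(edges: list[tuple[int, int]], weights: np.ndarray, m: int) -> int:
    """Extend an admission count to include the whole tie group at the cutoff.

    Binarization is threshold semantics: every edge whose |weight| equals the
    last admitted edge's is admitted too. This makes binarizing an
    already-binary connected matrix the identity, while leaving matrices
    with distinct weights untouched.
    """
    if m == 0 or m >= len(edges):
        return min(m, len(edges))
    cut = abs(weights[edges[m - 1]])
    while m < len(edges) and abs(weights[edges[m]]) == cut:
        m += 1
    return m


def minimum_density_edge_count(matrix: WeightedConnectivityMatrix) -> int:
    """Smallest number of top-|weight| edges that fully connects the network.

    Edges enter in descending |weight| (ties by lower row, then column
    index); the count is extended to the end of the cutoff tie group. Raises
    ValueError when no prefix of the ranked edge list connects the graph
    (e.g. an all-zero matrix).
    """
    n = matrix.n_regions
    edges = _ranked_edges(matrix.weights)
    uf = _UnionFind(n)
    for m, (i, j) in enumerate(edges, start=1):
        uf.union(i, j)
        if uf.n_components == 1:
            return _complete_ties(edges, matrix.weights, m)
    raise ValueError("matrix cannot be connected at any density")


def binarize_at_edge_count(matrix: WeightedConnectivityMatrix, m: int) -> BinaryNetwork:
    """Admit the top ``m`` edges by |weight|, completed to the cutoff tie group."""
    n = matrix.n_regions
    edges = _ranked_edges(matrix.weights)
    m = _complete_ties(edges, matrix.weights, m)
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges[:m]:
        adj[i, j] = adj[j, i] = 1
    n_pairs = n * (n - 1) // 2
    return BinaryNetwork(labels=list(matrix.labels), adjacency=adj,
                         density=int(adj.sum() // 2) / n_pairs)


def binarize_to_min_density(
    matrix: WeightedConnectivityMatrix,
    mode: Literal["per_subject", "cohort_common"] = "per_subject",
    cohort: Sequence[WeightedConnectivityMatrix] | None = None,
) -> BinaryNetwork:
    """Binarize at minimum connection density.

    ``per_subject`` stops at this subject's own minimum; ``cohort_common``
    applies the maximum of all cohort members' minimum edge counts, so every
    subject in the cohort shares one density.
    """
    if mode == "per_subject":
        m = minimum_density_edge_count(matrix)
    elif mode == "cohort_common":
        if not cohort:
            raise ValueError("cohort_common mode requires a cohort of matrices")
        for other in cohort:
            if other.labels != matrix.labels:
                raise ValueError("cohort matrices must share region labels")
        m = max(minimum_density_edge_count(mx) for mx in cohort)
    else:
        raise ValueError(f"unknown binarization mode: {mode!r}")
    return binarize_at_edge_count(matrix, m)


def binarize_cohort(
    matrices: Sequence[WeightedConnectivityMatrix],
    mode: Literal["per_subject", "cohort_common"] = "cohort_common",
) -> list[BinaryNetwork]:
    """Binarize every subject, sharing one density in ``cohort_common`` mode."""
    if mode == "cohort_common":
        m = max(minimum_density_edge_count(mx) for mx in matrices)
        return [binarize_at_edge_count(mx, m) for mx in matrices]
    return [binarize_to_min_density(mx, mode="per_subject") for mx in matrices]


def degree(net: BinaryNetwork) -> np.ndarray:
    return net.adjacency.sum(axis=1)


def clustering_coefficient(net: BinaryNetwork) -> np.ndarray:
    """Per-region C_i = 2 t_i / (k_i (k_i - 1)); zero when k_i < 2.

    t_i (triangles through i) comes from the diagonal of A^3.
    """
    a = net.adjacency.astype(float)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def betweenness_centrality(net: BinaryNetwork) -> np.ndarray:
    """Unnormalized shortest-path betweenness over unordered pairs."""
    g = nx.from_numpy_array(net.adjacency)
    b = nx.betweenness_centrality(g, normalized=False)
    return np.array([b[i] for i in range(net.n_regions)], dtype=float)


def detect_modules(net: BinaryNetwork, seed: int = 0) -> ModulePartition:
    """Greedy modularity maximization (Clauset–Newman–Moore agglomeration).

    The agglomeration is deterministic, so ``seed`` has no effect; it is kept
    in the signature so callers can thread a pipeline seed uniformly.
    """
    if net.n_regions < 2:
        raise ValueError("module detection requires at least 2 regions")
    g = nx.from_numpy_array(net.adjacency)
    communities = nx.community.greedy_modularity_communities(g)
    module_of = np.zeros(net.n_regions, dtype=int)
    for mid, members in enumerate(communities):
        for node in members:
            module_of[node] = mid
    q = modularity(net, module_of)
    return ModulePartition(labels=list(net.labels), module_of=module_of, modularity=q)


def modularity(net: BinaryNetwork, module_of: np.ndarray | ModulePartition) -> float:
    """Newman Q = sum_s (e_ss - a_s^2) for a given partition."""
    if isinstance(module_of, ModulePartition):
        module_of = module_of.module_of
    g = nx.from_numpy_array(net.adjacency)
    groups: dict[int, set[int]] = {}
    for node, mid in enumerate(np.asarray(module_of)):
        groups.setdefault(int(mid), set()).add(node)
    return float(nx.community.modularity(g, list(groups.values())))


def participation_coefficient(
    net: BinaryNetwork, partition: ModulePartition | np.ndarray
) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2; zero for isolated regions."""
    module_of = partition.module_of if isinstance(partition, ModulePartition) else np.asarray(partition)
    if module_of.shape[0] != net.n_regions:
        raise ValueError("partition does not cover all regions")
    a = net.adjacency
    k = a.sum(axis=1).astype(float)
    n_modules = int(module_of.max()) + 1
    # k_is: edges from region i into module s
    onehot = np.zeros((net.n_regions, n_modules))
    onehot[np.arange(net.n_regions), module_of] = 1.0
    kis = a @ onehot
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, kis / k[:, None], 0.0)
    p = 1.0 - (frac**2).sum(axis=1)
    return np.where(k > 0, p, 0.0)


def node_metric_table(
    net: BinaryNetwork, partition: ModulePartition | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-region metric table: degree, clustering, betweenness, module, participation."""
    if partition is None:
        partition = detect_modules(net, seed=seed)
    return pd.DataFrame(
        {
            "region": net.labels,
            "degree": degree(net),
            "clustering": clustering_coefficient(net),
            "betweenness": betweenness_centrality(net),
            "module": partition.module_of,
            "participation": participation_coefficient(net, partition),
        }
    )


def group_mean_network(nets: Sequence[BinaryNetwork]) -> BinaryNetwork:
    """Binary network of the group-mean adjacency, thresholded to min density.

    Averaging subjects' binary adjacencies gives an edge-frequency matrix;
    binarizing that at its own minimum connection density yields the group
    representative network used for the module partition behind hub typing.
    """
    if not nets:
        raise ValueError("empty group")
    labels = nets[0].labels
    mean_adj = np.mean([n.adjacency for n in nets], axis=0)
    mx = WeightedConnectivityMatrix(labels=list(labels), weights=mean_adj)
    return binarize_to_min_density(mx, mode="per_subject")


def classify_hubs(
    metrics: pd.DataFrame,
    participation_threshold: float = CONNECTOR_PARTICIPATION_THRESHOLD,
) -> pd.DataFrame:
    """Flag hub regions and type them provincial vs connector.

    ``metrics`` is a (typically group-mean) table with columns ``region``,
    ``degree``, ``betweenness``, ``clustering`` and ``participation``. A
    region is a hub when any of the three metrics exceeds that metric's mean
    over all regions by more than one standard deviation (sample SD). Hubs
    with participation above the threshold are connectors, the rest
    provincial. A metric with zero variance can mark no hubs.
    """
    out = metrics[["region"]].copy()
    qualifying: list[list[str]] = [[] for _ in range(len(metrics))]
    for col in ("degree", "betweenness", "clustering"):
        vals = metrics[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        cutoff = vals.mean() + sd
        if sd > 0:
            for idx in np.flatnonzero(vals > cutoff):
                qualifying[idx].append(col)
    out["is_hub"] = [len(q) > 0 for q in qualifying]
    out["qualifying_criteria"] = ["+".join(q) for q in qualifying]
    p = metrics["participation"].to_numpy(dtype=float)
    out["hub_type"] = np.where(
        ~out["is_hub"], "none",
        np.where(p > participation_threshold, "connector", "provincial"),
    )
    return out
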