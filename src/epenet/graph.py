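"""Weighted fully-connected network analysis.

Three complementary topological parameters on symmetric nonnegative
adjacency matrices (diagonal excluded):

Clustering coefficient (segregation)
    Geometric-mean triangle form,
    ``C_i = 2 sum_{j<k} (w_ij w_ik w_jk)^{1/3} / (k_i (k_i - 1))``,
    with weights first normalized by the maximum off-diagonal weight so
    C_i stays in [0, 1], and k_i the number of nonzero-weight neighbours.

Shortest paths (integration)
    All-pairs Dijkstra on distances ``d_ij = transform(w_ij)``.  The default
    transform is reciprocal (``d = 1/w``), so strong connectivity means short
    distance; a "literal" mode (``d = w``) treats the weights themselves as
    lengths.  Per node we report the mean shortest-path distance
    ``L_i = sum_j d_ij / (n - 1)`` and the mean number of edges (hops) on the
    n-1 optimal paths; the full node sequence of every pair's path is kept in
    a registry.  Ties between equal-length paths are broken toward fewer
    hops, then lexicographic node order, so the registry is deterministic.

Modularity (community structure)
    Louvain maximization of the standard Newman weighted modularity
    ``Q = (1/2m) sum_ij [w_ij - s_i s_j / 2m] delta(m_i, m_j)`` with s the
    node strengths and 2m the total weight; best partition over a number of
    seeded restarts.  A variant normalizer (the weighted characteristic path
    length) is available in :func:`modularity_score`.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from epenet.connectivity import AdjacencyMatrix
from epenet.montage import region_assignment

__all__ = [
    "Partition",
    "weighted_clustering",
    "shortest_paths",
    "modularity_partition",
    "modularity_score",
    "module_composition_report",
    "node_metric_table",
]


def _values(A) -> np.ndarray:
    v = A.values if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    v = v.copy()
    np.fill_diagonal(v, 0.0)
    if v.size and v.min() < 0:
        raise ValueError("adjacency weights must be nonnegative")
    return v


def weighted_clustering(A) -> np.ndarray:
    """Per-node weighted clustering coefficients in [0, 1].

    Weights are normalized by the maximum off-diagonal weight before the
    geometric-mean triangle sum, which makes the coefficient invariant under
    global rescaling of the matrix.  Nodes with fewer than two nonzero-weight
    neighbours get C_i = 0.
    """
    W = _values(A)
    n = W.shape[0]
    wmax = W.max()
    if wmax <= 0:
        return np.zeros(n)
    Wn = W / wmax
    A3 = np.cbrt(Wn)
    # sum over ordered (j, k) pairs of (w_ij w_ik w_jk)^{1/3} = (A3^3)_ii
    tri = np.diag(A3 @ A3 @ A3)
    k = np.count_nonzero(W > 0, axis=1)
    C = np.zeros(n)
    ok = k >= 2
    C[ok] = tri[ok] / (k[ok] * (k[ok] - 1))
    return C


def _distance_matrix(W: np.ndarray, transform: str) -> np.ndarray:
    if transform == "reciprocal":
        with np.errstate(divide="ignore"):
            D = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    elif transform == "literal":
        D = np.where(W > 0, W, np.inf)
    else:
        raise ValueError(f"unknown weight-to-distance transform {transform!r}")
    np.fill_diagonal(D, np.inf)  # no self-edges
    finite = D[np.isfinite(D)]
    if finite.size and finite.min() <= 0:
        raise ValueError("nonpositive distance after transform")
    return D


def _dijkstra_from(D: np.ndarray, src: int):
    """Single-source Dijkstra with deterministic tie-breaking.

    A node's settled label is the lexicographically minimal
    (distance, hops, node-sequence) triple, so among equal-distance paths the
    one with fewer edges wins, then the lexicographically smallest node
    sequence.
    """
    n = D.shape[0]
    best: dict[int, tuple[float, int, tuple[int, ...]]] = {}
    heap = [(0.0, 0, (src,))]
    while heap:
        dist, hops, path = heapq.heappop(heap)
        u = path[-1]
        if u in best:
            continue
        best[u] = (dist, hops, path)
        for v in range(n):
            if v not in best and np.isfinite(D[u, v]):
                heapq.heappush(heap, (dist + D[u, v], hops + 1, path + (v,)))
    return best


def shortest_paths(A, transform: str = "reciprocal"):
    """All-pairs weighted shortest paths.

    Returns ``(L, mean_edge_count, registry)`` where ``L[i]`` is the mean
    shortest-path distance from node i to the other n-1 nodes,
    ``mean_edge_count[i]`` the mean hop count of those n-1 optimal paths, and
    ``registry`` maps each ordered label pair to the node-label sequence of
    its optimal path.  Unreachable pairs yield infinite L (flagged by the
    caller); a disconnected graph is legal but reported as inf.
    """
    W = _values(A)
    n = W.shape[0]
    labels = (
        list(A.channel_labels)
        if isinstance(A, AdjacencyMatrix)
        else [str(i) for i in range(n)]
    )
    D = _distance_matrix(W, transform)
    L = np.zeros(n)
    hops = np.zeros(n)
    registry: dict[tuple[str, str], list[str]] = {}
    for i in range(n):
        best = _dijkstra_from(D, i)
        dsum = 0.0
        hsum = 0.0
        reach = 0
        for j in range(n):
            if j == i:
                continue
            if j in best:
                dist, h, path = best[j]
                dsum += dist
                hsum += h
                reach += 1
                registry[(labels[i], labels[j])] = [labels[p] for p in path]
            else:
                dsum = np.inf
        L[i] = dsum / (n - 1) if np.isfinite(dsum) else np.inf
        hops[i] = hsum / reach if reach else np.nan
    return L, hops, registry


def node_metric_table(A, transform: str = "reciprocal") -> pd.DataFrame:
    """Per-electrode clustering, weighted path length and mean hop count."""
    C = weighted_clustering(A)
    L, hops, _ = shortest_paths(A, transform=transform)
    labels = (
        list(A.channel_labels)
        if isinstance(A, AdjacencyMatrix)
        else [str(i) for i in range(len(C))]
    )
    df = pd.DataFrame(
        {"electrode": labels, "clustering": C, "path_length": L, "mean_edge_count": hops}
    )
    if isinstance(A, AdjacencyMatrix):
        df.attrs.update({"measure": A.measure, "band": A.band.name, "tag": A.tag})
    return df


@dataclass(frozen=True)
class Partition:
    """Assignment of nodes to modules with its modularity score Q."""

    membership: dict[str, int]
    q: float
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mods = self.modules
        if any(len(m) == 0 for m in mods.values()):
            raise ValueError("modules must be non-empty")

    @property
    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, m in self.membership.items():
            out.setdefault(m, []).append(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))


def modularity_score(A, membership, normalizer: str = "total_weight") -> float:
    """Newman weighted modularity of a given partition.

    ``normalizer="total_weight"`` is the standard form (1/2m with 2m the
    total edge weight).  ``normalizer="char_path_length"`` replaces 2m by the
    weighted characteristic path length (mean of the per-node shortest-path
    lengths under the reciprocal transform) — a printed variant, provided for
    comparison, with no claim to superiority.
    """
    W = _values(A)
    n = W.shape[0]
    labels = (
        list(A.channel_labels)
        if isinstance(A, AdjacencyMatrix)
        else [str(i) for i in range(n)]
    )
    if isinstance(membership, dict):
        comm = np.array([membership[lab] for lab in labels])
    else:
        comm = np.asarray(membership, dtype=int)
    strength = W.sum(axis=1)
    two_m = W.sum()
    if two_m <= 0:
        raise ValueError("modularity of an all-zero matrix is undefined")
    if normalizer == "total_weight":
        norm = two_m
    elif normalizer == "char_path_length":
        L, _, _ = shortest_paths(A if isinstance(A, AdjacencyMatrix) else W)
        norm = float(np.mean(L))
        if not np.isfinite(norm) or norm <= 0:
            raise ValueError("characteristic path length normalizer is degenerate")
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    same = comm[:, None] == comm[None, :]
    q = (W - np.outer(strength, strength) / norm)[same].sum() / norm
    return float(q)


def modularity_partition(
    A,
    seed: int = 0,
    n_restarts: int = 8,
    resolution: float = 1.0,
    tags: dict | None = None,
) -> Partition:
    """Louvain modularity maximization with seeded restarts.

    Returns the best partition found over ``n_restarts`` Louvain runs,
    scored by the standard Newman weighted Q.  Deterministic under a fixed
    seed.
    """
    W = _values(A)
    if W.sum() <= 0:
        raise ValueError("modularity of an all-zero matrix is undefined")
    n = W.shape[0]
    labels = (
        list(A.channel_labels)
        if isinstance(A, AdjacencyMatrix)
        else [str(i) for i in range(n)]
    )
    G = nx.from_numpy_array(W)
    best_q = -np.inf
    best_membership: dict[str, int] | None = None
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed + r
        )
        membership = {}
        for m, nodes in enumerate(sorted(comms, key=min)):
            for node in nodes:
                membership[labels[node]] = m
        q = modularity_score(A if isinstance(A, AdjacencyMatrix) else W, membership)
        if q > best_q + 1e-15:
            best_q = q
            best_membership = membership
    assert best_membership is not None
    base_tags = dict(tags or {})
    if isinstance(A, AdjacencyMatrix):
        base_tags.setdefault("measure", A.measure)
        base_tags.setdefault("band", A.band.name)
        base_tags.setdefault("tag", A.tag)
    return Partition(membership=best_membership, q=best_q, tags=base_tags)


def module_composition_report(
    partition: Partition,
    channel_labels,
    montage_regions: dict[str, str] | None = None,
) -> dict:
    """Module compositions plus the per-region spread over modules.

    ``region_spread[r]`` counts how many distinct modules region r's
    electrodes occupy (1 = the region stays together).
    """
    labels = list(channel_labels)
    if set(labels) != set(partition.membership):
        missing = set(labels) ^ set(partition.membership)
        raise ValueError(f"channel labels do not match partition nodes: {sorted(missing)}")
    if montage_regions is None:
        montage_regions = dict(zip(labels, region_assignment(labels)))
    modules = {
        m: [lab for lab in labels if partition.membership[lab] == m]
        for m in sorted(set(partition.membership.values()))
    }
    region_spread: dict[str, int] = {}
    for region in sorted(set(montage_regions.values())):
        mods = {partition.membership[lab] for lab in labels if montage_regions[lab] == region}
        region_spread[region] = len(mods)
    return {
        "n_modules": partition.n_modules,
        "q": partition.q,
        "modules": {
            str(m): {
                "electrodes": labs,
                "regions": sorted({montage_regions[l] for l in labs}),
            }
            for m, labs in modules.items()
        },
        "region_spread": region_spread,
        "tags": partition.tags,
    }
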