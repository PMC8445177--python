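"""Final cluster construction via maximal-clique merging (step 4).

Candidate clusters are first grouped by the label of their middle point
(position 11) inherited from step 1.  Within each group a simple undirected
graph is built: vertices are candidates, and an edge joins two candidates
whose centroids lie within d_Mmax (default 6 mm, strict) under the
orientation-invariant distance d_ME.  All maximal cliques of the graph are
enumerated (Bron-Kerbosch with pivoting over a degeneracy vertex ordering,
efficient on the sparse graphs this refinement step produces) and processed
in decreasing size; each clique merges its not-yet-consumed members into
one final cluster, so every candidate ends in exactly one final cluster.

An optional post-filter removes final clusters whose intra-cluster
distance (max member-to-centroid d_ME) exceeds a threshold (70 mm in the
filtered pipeline variant), moving their fibers to the noise set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .metrics import ClusterStats, centroid, cluster_stats, pairwise_min_distance
from .reassignment import CandidateCluster

__all__ = [
    "ClusterGraph",
    "FinalCluster",
    "FinalClustering",
    "group_by_middle",
    "build_cluster_graph",
    "enumerate_maximal_cliques",
    "merge_by_cliques",
    "build_final_clusters",
    "filter_by_intra_distance",
    "D_MMAX",
]

#: Edge threshold in mm for the candidate-centroid graph (strict less-than).
D_MMAX = 6.0


@dataclass(frozen=True)
class FinalCluster:
    fiber_ids: tuple
    centroid: np.ndarray
    stats: ClusterStats

    @property
    def size(self) -> int:
        return len(self.fiber_ids)


@dataclass
class FinalClustering:
    """Partition of fiber ids into final clusters plus a discarded set."""

    clusters: list[FinalCluster]
    noise_ids: frozenset
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def clustered_ids(self) -> frozenset:
        return frozenset(i for c in self.clusters for i in c.fiber_ids)

    def labels(self, n_total: int) -> np.ndarray:
        """Per-fiber cluster index; -1 marks noise/unassigned."""
        lab = np.full(n_total, -1, dtype=int)
        for ci, c in enumerate(self.clusters):
            lab[list(c.fiber_ids)] = ci
        return lab


def group_by_middle(candidates: list[CandidateCluster],
                    middle_column: int) -> dict[int, list[int]]:
    """Partition candidate indices by the middle-position key component."""
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(candidates):
        groups.setdefault(int(c.key[middle_column]), []).append(i)
    return groups


def build_cluster_graph(centroids: np.ndarray, d_mmax: float = D_MMAX) -> nx.Graph:
    """Graph over one group's candidate centroids.

    Vertices are 0..m-1; edge (u, v) iff d_ME(centroid_u, centroid_v) is
    strictly below ``d_mmax``.
    """
    centroids = np.asarray(centroids, dtype=float)
    m = centroids.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(m))
    if m > 1:
        d = pairwise_min_distance(centroids, centroids)
        iu, ju = np.triu_indices(m, k=1)
        close = d[iu, ju] < d_mmax
        g.add_edges_from(zip(iu[close].tolist(), ju[close].tolist()))
    return g


def _degeneracy_ordering(adj: dict) -> list:
    """Vertex order by repeatedly removing a minimum-degree vertex."""
    degrees = {v: len(nb) for v, nb in adj.items()}
    buckets: dict[int, set] = {}
    for v, d in degrees.items():
        buckets.setdefault(d, set()).add(v)
    removed = set()
    order = []
    n = len(adj)
    while len(order) < n:
        d = min(b for b in buckets if buckets[b])
        v = min(buckets[d])  # deterministic tie-break
        buckets[d].discard(v)
        removed.add(v)
        order.append(v)
        for w in adj[v]:
            if w in removed:
                continue
            buckets[degrees[w]].discard(w)
            degrees[w] -= 1
            buckets.setdefault(degrees[w], set()).add(w)
    return order


def _bron_kerbosch_pivot(R: set, P: set, X: set, adj: dict, out: list) -> None:
    if not P and not X:
        out.append(frozenset(R))
        return
    pivot = max(P | X, key=lambda u: (len(P & adj[u]), -u))
    for v in sorted(P - adj[pivot]):
        _bron_kerbosch_pivot(R | {v}, P & adj[v], X & adj[v], adj, out)
        P = P - {v}
        X = X | {v}


def enumerate_maximal_cliques(g: nx.Graph) -> list[frozenset]:
    """All maximal cliques of a simple graph.

    Outer loop over a degeneracy vertex ordering, pivoting Bron-Kerbosch
    inside; isolated vertices yield singleton cliques.
    """
    adj = {v: set(g.neighbors(v)) - {v} for v in g.nodes}
    order = _degeneracy_ordering(adj)
    pos = {v: i for i, v in enumerate(order)}
    out: list[frozenset] = []
    for v in order:
        later = {w for w in adj[v] if pos[w] > pos[v]}
        earlier = {w for w in adj[v] if pos[w] < pos[v]}
        _bron_kerbosch_pivot({v}, later, earlier, adj, out)
    return out


def merge_by_cliques(cliques: Iterable[frozenset],
                     n_vertices: int) -> list[tuple]:
    """Assign each vertex to the first clique (decreasing size) that
    reaches it.

    Cliques are processed by decreasing vertex count, ties broken by the
    lexicographically smallest sorted vertex tuple; a vertex consumed by an
    earlier clique is skipped by later ones.  Returns the merged vertex
    groups, each a sorted tuple, in processing order.
    """
    ordered = sorted(cliques, key=lambda c: (-len(c), tuple(sorted(c))))
    consumed: set = set()
    merged: list[tuple] = []
    for cl in ordered:
        free = sorted(set(cl) - consumed)
        if free:
            merged.append(tuple(free))
            consumed.update(free)
    # isolated vertices always form singleton maximal cliques, so every
    # vertex is covered; guard anyway for malformed input
    for v in range(n_vertices):
        if v not in consumed:
            merged.append((v,))
            consumed.add(v)
    return merged


def build_final_clusters(
    candidates: list[CandidateCluster],
    t,
    noise_ids: Iterable[int],
    middle_column: int,
    d_mmax: float = D_MMAX,
    align: bool = True,
    params: dict | None = None,
) -> FinalClustering:
    """Run the full step: group by middle label, build graphs, merge cliques.

    Merged centroids are recomputed with flip alignment over the union of
    member fibers; per-cluster dispersion stats are attached.
    """
    points = t.points
    groups = group_by_middle(candidates, middle_column)
    clusters: list[FinalCluster] = []
    for label in sorted(groups):
        idx = groups[label]
        cents = np.stack([candidates[i].centroid for i in idx])
        g = build_cluster_graph(cents, d_mmax)
        cliques = enumerate_maximal_cliques(g)
        for members in merge_by_cliques(cliques, len(idx)):
            ids = tuple(sorted(
                fid for m in members for fid in candidates[idx[m]].fiber_ids
            ))
            if len(members) == 1:
                cen = candidates[idx[members[0]]].centroid
            else:
                cen = centroid(points[list(ids)], align=align)
            clusters.append(FinalCluster(
                fiber_ids=ids,
                centroid=cen,
                stats=cluster_stats(points[list(ids)], cen),
            ))
    return FinalClustering(
        clusters=clusters,
        noise_ids=frozenset(int(i) for i in noise_ids),
        params=dict(params or {}),
    )


def filter_by_intra_distance(fc: FinalClustering,
                             max_intra: float = 70.0) -> FinalClustering:
    """Drop clusters whose intra-cluster distance exceeds ``max_intra`` mm
    (strict), moving their fibers to the noise set."""
    kept = [c for c in fc.clusters if c.stats.intra_distance <= max_intra]
    dropped = [c for c in fc.clusters if c.stats.intra_distance > max_intra]
    noise = set(fc.noise_ids)
    for c in dropped:
        noise.update(c.fiber_ids)
    params = dict(fc.params)
    params["intra_filter_mm"] = max_intra
    return FinalClustering(clusters=kept, noise_ids=frozenset(noise), params=params)
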