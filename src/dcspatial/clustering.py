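"""Density-based clustering (DBC) of dendritic cells.

The partition rule: for each DC p, count the DCs n(p) inside the closed
disc of radius R centred on p (p itself included). If n(p) >= D, every DC
in that disc receives p's provisional cluster label; provisional clusters
that share any member are merged to transitive closure; DCs left without
a label are noise and excluded from all cluster statistics.

This differs from DBSCAN: there is no single-assignment of border points —
any overlap between the discs of two core points merges their clusters
outright.

Boundary conventions (made explicit because the algorithm description
leaves them open): distance <= R counts as inside the disc, and n(p)
counts p itself, so five coincident DCs form a cluster at D = 5.

`dbc_cluster` uses a k-d tree and union-find and scales to tens of
thousands of DCs; `dbc_oracle` re-derives the same partition by explicit
set construction and graph connected components, as an independent
reference for testing (quadratic, intended for small inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import Cell, CellMap, IntegrityError

__all__ = [
    "NOISE",
    "ClusterParams",
    "ClusterAssignment",
    "ClusterSummary",
    "dbc_cluster",
    "dbc_oracle",
    "summarize_clusters",
]

#: Label for DCs that belong to no cluster.
NOISE = -1


@dataclass(frozen=True)
class ClusterParams:
    """Neighborhood radius R (pixels) and minimum neighbor count D."""

    R: float = 250.0
    D: int = 5

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"radius R must be > 0, got {self.R}")
        if self.D < 1:
            raise ValueError(f"density D must be >= 1, got {self.D}")


@dataclass
class ClusterAssignment:
    """Per-DC cluster labels for one cell map.

    ``dc_ids[i]`` is the cell_id of the i-th DC (map order) and
    ``labels[i]`` its cluster label (0..k-1) or :data:`NOISE`. ``clusters``
    lists the member cell_id sets, indexed by label.
    """

    node_id: str
    dc_ids: list[int]
    labels: list[int]
    clusters: list[set[int]] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.dc_ids) != len(self.labels):
            raise IntegrityError("dc_ids and labels length mismatch")
        k = max(self.labels, default=NOISE) + 1
        clusters: list[set[int]] = [set() for _ in range(k)]
        for cid, lab in zip(self.dc_ids, self.labels):
            if lab != NOISE:
                clusters[lab].add(cid)
        if any(not c for c in clusters):
            raise IntegrityError("empty cluster label in assignment")
        self.clusters = clusters

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def label_of(self, cell_id: int) -> int:
        try:
            return self.labels[self.dc_ids.index(cell_id)]
        except ValueError:
            raise IntegrityError(f"cell_id {cell_id} is not a DC of this assignment") from None

    def clustered_ids(self) -> set[int]:
        return {cid for cid, lab in zip(self.dc_ids, self.labels) if lab != NOISE}

    def noise_ids(self) -> set[int]:
        return {cid for cid, lab in zip(self.dc_ids, self.labels) if lab == NOISE}


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def dbc_cluster(cell_map: CellMap, params: ClusterParams = ClusterParams()) -> ClusterAssignment:
    """Partition the DCs of ``cell_map`` into density-based clusters.

    Only DCs (immature + mature) enter the point set; all other phenotypes
    are ignored. Returns a deterministic assignment: the output is
    invariant to permutation of the input rows.
    """
    dcs = cell_map.dcs()
    dc_ids = [c.cell_id for c in dcs]
    n = len(dcs)
    if n == 0:
        return ClusterAssignment(cell_map.node_id, [], [])

    # Re-index DCs by ascending cell_id so the union-find is order-free.
    order = sorted(range(n), key=lambda i: dc_ids[i])
    pts = cell_map.coords(dcs)[order]
    ids_sorted = [dc_ids[i] for i in order]

    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, r=params.R)  # closed disc, self included

    uf = _UnionFind(n)
    in_cluster = np.zeros(n, dtype=bool)
    for p, neigh in enumerate(neighborhoods):
        if len(neigh) >= params.D:  # p is a core point
            in_cluster[p] = True
            for q in neigh:
                in_cluster[q] = True
                uf.union(p, q)

    groups: dict[int, set[int]] = {}
    for i in range(n):
        if in_cluster[i]:
            groups.setdefault(uf.find(i), set()).add(i)

    # Map member indices back to cell_ids before canonical labeling.
    id_groups = [{ids_sorted[i] for i in g} for g in groups.values()]
    labels_by_id = _labels_from_groups(dc_ids, id_groups)
    return ClusterAssignment(cell_map.node_id, dc_ids, labels_by_id)


def _labels_from_groups(dc_ids: list[int], id_groups: list[set[int]]) -> list[int]:
    ordered = sorted(id_groups, key=min)
    label_of = {cid: lab for lab, members in enumerate(ordered) for cid in members}
    return [label_of.get(cid, NOISE) for cid in dc_ids]


def dbc_oracle(cell_map: CellMap, params: ClusterParams = ClusterParams()) -> ClusterAssignment:
    """Reference implementation by explicit construction (quadratic).

    Marks core DCs from the full pairwise distance matrix, builds one
    provisional member set per core, connects intersecting sets in a graph,
    and takes connected components as clusters. Intended for inputs up to
    a few thousand DCs; used to validate :func:`dbc_cluster`.
    """
    dcs = cell_map.dcs()
    dc_ids = [c.cell_id for c in dcs]
    n = len(dcs)
    if n == 0:
        return ClusterAssignment(cell_map.node_id, [], [])

    pts = cell_map.coords(dcs)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    within = dist <= params.R

    provisional: list[frozenset[int]] = [
        frozenset(np.flatnonzero(within[p])) for p in range(n) if within[p].sum() >= params.D
    ]

    g = nx.Graph()
    g.add_nodes_from(range(len(provisional)))
    for i in range(len(provisional)):
        for j in range(i + 1, len(provisional)):
            if provisional[i] & provisional[j]:
                g.add_edge(i, j)

    id_groups = []
    for comp in nx.connected_components(g):
        members: set[int] = set()
        for v in comp:
            members |= provisional[v]
        id_groups.append({dc_ids[i] for i in members})

    return ClusterAssignment(cell_map.node_id, dc_ids, _labels_from_groups(dc_ids, id_groups))


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    size: int
    mature_count: int
    centroid: tuple[float, float]


def summarize_clusters(
    assignment: ClusterAssignment, cell_map: CellMap
) -> list[ClusterSummary]:
    """Per-cluster size, mature-DC count and centroid (mean coordinates)."""
    if assignment.node_id != cell_map.node_id:
        raise IntegrityError(
            f"assignment is for node {assignment.node_id!r}, map is {cell_map.node_id!r}"
        )
    by_id: dict[int, Cell] = {c.cell_id: c for c in cell_map.dcs()}
    if set(assignment.dc_ids) != set(by_id):
        raise IntegrityError("assignment DC set does not match the cell map")
    out = []
    for lab, members in enumerate(assignment.clusters):
        cells = [by_id[cid] for cid in members]
        xs = np.array([c.x for c in cells])
        ys = np.array([c.y for c in cells])
        mature = sum(c.phenotype.name == "MATURE_DC" for c in cells)
        out.append(
            ClusterSummary(
                cluster_id=lab,
                size=len(cells),
                mature_count=mature,
                centroid=(float(xs.mean()), float(ys.mean())),
            )
        )
    return out
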