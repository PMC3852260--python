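"""Per-node spatial and maturity metrics.

All quantities are normalized by cell counts (not area) to absorb the
large variation in lymph-node section size:

- ``pct_dcs`` / ``pct_t_cells``: percentages of the T + DC + OTHER cell
  total (tumor and B cells are excluded from this denominator by default;
  ``include_all_non_tumor`` widens it to every non-tumor cell).
- ``pct_mature_dcs``: CD83+ DCs as a percentage of all DCs.
- ``pct_clustered_dcs``: DCs assigned to any density-based cluster, as a
  percentage of all DCs.
- ``rel_cluster_count``: clusters per DC (dimensionless; conventionally
  reported x10^-3).
- ``mean_cluster_size``: mean member count over the node's clusters.
- ``pct_mature_clustered``: CD83+ DCs among clustered DCs.

A field whose denominator is zero is ``None`` (missing), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .clustering import ClusterAssignment
from .core import CellMap, IntegrityError, Phenotype

__all__ = ["NodeMetrics", "compute_node_metrics"]


@dataclass(frozen=True)
class NodeMetrics:
    node_id: str
    n_total_cells: int
    n_dcs: int
    n_clusters: int
    pct_dcs: float | None
    pct_mature_dcs: float | None
    pct_clustered_dcs: float | None
    rel_cluster_count: float | None
    mean_cluster_size: float | None
    pct_mature_clustered: float | None
    pct_t_cells: float | None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def compute_node_metrics(
    cell_map: CellMap,
    assignment: ClusterAssignment,
    include_all_non_tumor: bool = False,
) -> NodeMetrics:
    """Compute the full per-node metric vector.

    ``assignment`` must have been produced from ``cell_map``.
    """
    if assignment.node_id != cell_map.node_id:
        raise IntegrityError(
            f"assignment is for node {assignment.node_id!r}, map is {cell_map.node_id!r}"
        )
    dc_ids = {c.cell_id for c in cell_map.dcs()}
    if set(assignment.dc_ids) != dc_ids:
        raise IntegrityError("assignment DC set does not match the cell map")

    counts = {p: 0 for p in Phenotype}
    for c in cell_map.cells:
        counts[c.phenotype] += 1
    n_dcs = counts[Phenotype.IMMATURE_DC] + counts[Phenotype.MATURE_DC]
    n_t = counts[Phenotype.T_CELL]
    denom = n_t + n_dcs + counts[Phenotype.OTHER]
    if include_all_non_tumor:
        denom += counts[Phenotype.B_CELL]

    n_mature = counts[Phenotype.MATURE_DC]
    clustered = assignment.clustered_ids()
    mature_ids = {c.cell_id for c in cell_map.cells if c.phenotype is Phenotype.MATURE_DC}
    n_clustered = len(clustered)
    n_mature_clustered = len(clustered & mature_ids)
    sizes = [len(c) for c in assignment.clusters]

    return NodeMetrics(
        node_id=cell_map.node_id,
        n_total_cells=len(cell_map),
        n_dcs=n_dcs,
        n_clusters=assignment.n_clusters,
        pct_dcs=_pct(n_dcs, denom),
        pct_mature_dcs=_pct(n_mature, n_dcs),
        pct_clustered_dcs=_pct(n_clustered, n_dcs),
        rel_cluster_count=(assignment.n_clusters / n_dcs) if n_dcs else None,
        mean_cluster_size=(sum(sizes) / len(sizes)) if sizes else None,
        pct_mature_clustered=_pct(n_mature_clustered, n_clustered),
        pct_t_cells=_pct(n_t, denom),
    )
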