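"""DC-T cell co-localization.

A T cell is considered associated with a DC when it lies within a fixed
influence radius (default 100 pixels, roughly the diameter of a DC
including its dendrites in the source images). Two counting modes:

- NEAREST: each T cell is assigned to its single nearest DC, provided
  that DC is within the radius (ties broken by smallest DC cell_id).
- ALL_WITHIN: each T cell counts toward every DC within the radius.

The per-DC T-cell counts are then compared between clustered and
unclustered (noise) DCs. Only center-to-center Euclidean distance in
pixels is used; no cell-shape or diffusion modeling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .clustering import NOISE, ClusterAssignment
from .core import CellMap, IntegrityError, Phenotype

__all__ = ["ColocMode", "ColocParams", "TAssociation", "associate_t_cells", "coloc_summary"]


class ColocMode(enum.Enum):
    NEAREST = "nearest"
    ALL_WITHIN = "all_within"


@dataclass(frozen=True)
class ColocParams:
    radius: float = 100.0
    mode: ColocMode = ColocMode.NEAREST

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass
class TAssociation:
    """Per-T-cell associated DCs and per-DC T-cell counts.

    ``associated_dc_ids[t]`` is empty for an unassociated T cell, a
    singleton in NEAREST mode, possibly larger in ALL_WITHIN mode.
    """

    node_id: str
    mode: ColocMode
    t_cell_ids: list[int]
    associated_dc_ids: dict[int, list[int]]
    t_count: dict[int, int] = field(default_factory=dict)  # per DC

    def n_associated(self) -> int:
        return sum(1 for v in self.associated_dc_ids.values() if v)


def associate_t_cells(cell_map: CellMap, params: ColocParams = ColocParams()) -> TAssociation:
    """Associate each T cell of ``cell_map`` with DC(s) within the radius.

    Boundary inclusive: distance exactly equal to the radius associates.
    """
    dcs = cell_map.dcs()
    ts = cell_map.subset([Phenotype.T_CELL])
    dc_ids = [c.cell_id for c in dcs]
    t_ids = [c.cell_id for c in ts]
    t_count = {cid: 0 for cid in dc_ids}
    assoc: dict[int, list[int]] = {tid: [] for tid in t_ids}

    if dcs and ts:
        tree = cKDTree(cell_map.coords(dcs))
        t_pts = cell_map.coords(ts)
        hits = tree.query_ball_point(t_pts, r=params.radius)
        for t_idx, dc_idxs in enumerate(hits):
            if not dc_idxs:
                continue
            if params.mode is ColocMode.NEAREST:
                tp = t_pts[t_idx]
                best = min(
                    dc_idxs,
                    key=lambda i: (np.hypot(dcs[i].x - tp[0], dcs[i].y - tp[1]), dc_ids[i]),
                )
                chosen = [best]
            else:
                chosen = sorted(dc_idxs, key=lambda i: dc_ids[i])
            for i in chosen:
                assoc[t_ids[t_idx]].append(dc_ids[i])
                t_count[dc_ids[i]] += 1

    return TAssociation(
        node_id=cell_map.node_id,
        mode=params.mode,
        t_cell_ids=t_ids,
        associated_dc_ids=assoc,
        t_count=t_count,
    )


def coloc_summary(
    assoc: TAssociation, assignment: ClusterAssignment
) -> tuple[float | None, float | None]:
    """Mean T-cell count per clustered DC and per unclustered (noise) DC.

    Either mean is ``None`` when its DC stratum is empty. ``assoc`` and
    ``assignment`` must come from the same cell map.
    """
    if assoc.node_id != assignment.node_id:
        raise IntegrityError(
            f"association is for node {assoc.node_id!r}, assignment is {assignment.node_id!r}"
        )
    if set(assoc.t_count) != set(assignment.dc_ids):
        raise IntegrityError("association DC set does not match the cluster assignment")
    clustered = [
        assoc.t_count[cid]
        for cid, lab in zip(assignment.dc_ids, assignment.labels)
        if lab != NOISE
    ]
    unclustered = [
        assoc.t_count[cid]
        for cid, lab in zip(assignment.dc_ids, assignment.labels)
        if lab == NOISE
    ]
    mean_c = float(np.mean(clustered)) if clustered else None
    mean_u = float(np.mean(unclustered)) if unclustered else None
    return mean_c, mean_u
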