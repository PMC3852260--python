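"""Domain types and file I/O for lymph-node cell-coordinate maps.

A *cell map* is the coordinate output of a cell-classification system run
on a stained lymph-node section: one row per identified cell with its
(x, y) position in pixels and a phenotype label derived from the IHC
markers (CD1a, CD83, CD3, CD20, pan-cytokeratin, hematoxylin).

Coordinate convention: origin at the top-left of the image, x rightward,
y downward, continuous pixel units. No conversion to physical units is
attempted; all downstream distances (cluster radius, co-localization
radius) are in the same pixel units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phenotype",
    "Cell",
    "CellMap",
    "NodeGroup",
    "NodeMetadata",
    "FormatError",
    "IntegrityError",
    "read_cell_map",
    "write_cell_map",
    "read_metadata",
    "write_metadata",
    "read_cohort",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV layout."""


class IntegrityError(ValueError):
    """Cross-record consistency violation (duplicate ids, unmatched joins)."""


class Phenotype(enum.Enum):
    """Closed phenotype vocabulary.

    IMMATURE_DC: CD1a+/CD83- dendritic cell.
    MATURE_DC:   CD83+ dendritic cell (with or without CD1a; maturity is
                 defined by CD83 positivity alone).
    T_CELL:      CD3+.
    B_CELL:      CD20+.
    TUMOR:       pan-cytokeratin+.
    OTHER:       hematoxylin-only nucleus.
    """

    IMMATURE_DC = "IMMATURE_DC"
    MATURE_DC = "MATURE_DC"
    T_CELL = "T_CELL"
    B_CELL = "B_CELL"
    TUMOR = "TUMOR"
    OTHER = "OTHER"

    @property
    def is_dc(self) -> bool:
        return self in (Phenotype.IMMATURE_DC, Phenotype.MATURE_DC)


@dataclass(frozen=True)
class Cell:
    cell_id: int
    x: float
    y: float
    phenotype: Phenotype


@dataclass
class CellMap:
    """All classified cells of one lymph-node section.

    ``extent``, when given, is the (width, height) of the source image in
    pixels; every coordinate must then lie inside ``[0, width] x [0, height]``.
    """

    node_id: str
    cells: list[Cell] = field(default_factory=list)
    extent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            seen: set[int] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise IntegrityError(f"duplicate cell_id {dup} in node {self.node_id!r}")
        if self.extent is not None:
            w, h = self.extent
            for c in self.cells:
                if not (0 <= c.x <= w and 0 <= c.y <= h):
                    raise IntegrityError(
                        f"cell {c.cell_id} at ({c.x}, {c.y}) outside extent {self.extent}"
                    )

    def __len__(self) -> int:
        return len(self.cells)

    def subset(self, phenotypes: Iterable[Phenotype]) -> list[Cell]:
        wanted = set(phenotypes)
        return [c for c in self.cells if c.phenotype in wanted]

    def dcs(self) -> list[Cell]:
        """The DC point set: all immature and mature dendritic cells."""
        return [c for c in self.cells if c.phenotype.is_dc]

    def coords(self, cells: Sequence[Cell] | None = None) -> np.ndarray:
        """(n, 2) array of x, y coordinates, in row order."""
        src = self.cells if cells is None else cells
        if not src:
            return np.empty((0, 2), dtype=float)
        return np.array([(c.x, c.y) for c in src], dtype=float)


class NodeGroup(enum.Enum):
    HLN = "HLN"  # healthy intramammary node (control)
    NSLN_NEG = "NSLN_NEG"  # tumor-free non-sentinel node
    NSLN_POS = "NSLN_POS"  # tumor-involved non-sentinel node


@dataclass(frozen=True)
class NodeMetadata:
    node_id: str
    group: NodeGroup
    patient_id: str
    followup_years: float
    relapse_event: bool
    concurrent_cancer: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.followup_years) or self.followup_years < 0:
            raise ValueError(f"followup_years must be finite and >= 0, got {self.followup_years}")


_CELL_COLUMNS = ["cell_id", "x", "y", "phenotype"]
_META_COLUMNS = [
    "node_id",
    "group",
    "patient_id",
    "followup_years",
    "relapse_event",
    "concurrent_cancer",
]


def _parse_phenotype(
    raw: str, row: int, vocabulary: Mapping[str, Phenotype] | None
) -> Phenotype:
    key = str(raw).strip().upper()
    if vocabulary is not None and key in vocabulary:
        return vocabulary[key]
    try:
        return Phenotype[key]
    except KeyError:
        raise ValueError(f"unknown phenotype {raw!r} at data row {row}") from None


def read_cell_map(
    path: str | Path,
    node_id: str | None = None,
    extent: tuple[float, float] | None = None,
    vocabulary: Mapping[str, Phenotype] | None = None,
) -> CellMap:
    """Read a cell-map CSV (columns ``cell_id,x,y,phenotype``).

    Row order is preserved. Phenotype strings are matched case-insensitively
    against the closed vocabulary; ``vocabulary`` may map additional
    (upper-cased) user strings onto enum members. ``node_id`` defaults to
    the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"phenotype": str})
    missing = [c for c in _CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if vocabulary is not None:
        vocabulary = {k.upper(): v for k, v in vocabulary.items()}
    cells = [
        Cell(
            cell_id=int(row.cell_id),
            x=float(row.x),
            y=float(row.y),
            phenotype=_parse_phenotype(row.phenotype, i, vocabulary),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    return CellMap(node_id=node_id or path.stem, cells=cells, extent=extent)


def write_cell_map(cell_map: CellMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cell_map.cells],
            "x": [c.x for c in cell_map.cells],
            "y": [c.y for c in cell_map.cells],
            "phenotype": [c.phenotype.value for c in cell_map.cells],
        }
    )
    df.to_csv(path, index=False)


def _parse_bool(raw: object) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    s = str(raw).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {raw!r}")


def read_metadata(path: str | Path) -> list[NodeMetadata]:
    """Read the cohort metadata CSV, one row per node."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            NodeMetadata(
                node_id=str(row.node_id),
                group=NodeGroup[str(row.group).strip().upper()],
                patient_id=str(row.patient_id),
                followup_years=float(row.followup_years),
                relapse_event=_parse_bool(row.relapse_event),
                concurrent_cancer=_parse_bool(row.concurrent_cancer),
            )
        )
    ids = [m.node_id for m in records]
    if len(ids) != len(set(ids)):
        raise IntegrityError(f"{path}: duplicate node_id values")
    return records


def write_metadata(records: Sequence[NodeMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "node_id": [m.node_id for m in records],
            "group": [m.group.value for m in records],
            "patient_id": [m.patient_id for m in records],
            "followup_years": [m.followup_years for m in records],
            "relapse_event": [m.relapse_event for m in records],
            "concurrent_cancer": [m.concurrent_cancer for m in records],
        }
    )
    df.to_csv(path, index=False)


def read_cohort(
    path_metadata: str | Path, paths_maps: Sequence[str | Path]
) -> list[tuple[CellMap, NodeMetadata]]:
    """Join a metadata table with its per-node cell maps.

    Every node_id in the metadata must have exactly one map file (matched
    by file stem) and vice versa; the joined cohort preserves metadata row
    order.
    """
    metadata = read_metadata(path_metadata)
    maps = {Path(p).stem: Path(p) for p in paths_maps}
    meta_ids = {m.node_id for m in metadata}
    missing_maps = sorted(meta_ids - maps.keys())
    orphan_maps = sorted(maps.keys() - meta_ids)
    if missing_maps or orphan_maps:
        parts = []
        if missing_maps:
            parts.append(f"metadata nodes without a map: {missing_maps}")
        if orphan_maps:
            parts.append(f"maps without a metadata row: {orphan_maps}")
        raise IntegrityError("; ".join(parts))
    return [(read_cell_map(maps[m.node_id]), m) for m in metadata]
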