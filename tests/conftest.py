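import pytest

from dcspatial import Cell, CellMap, Phenotype


def make_map(spec, node_id="test"):
    """Build a CellMap from (x, y, phenotype) tuples; cell_ids sequential."""
    cells = [Cell(i, float(x), float(y), p) for i, (x, y, p) in enumerate(spec)]
    return CellMap(node_id=node_id, cells=cells)


@pytest.fixture
def bridge_map():
    """Two 6-DC blobs at (0,0) and (480,0) joined by one bridge DC at (240,0).

    At R=250, D=5 the bridge lies inside the core circle of both blobs,
    which forces the merge step to produce a single 13-DC cluster.
    """
    spec = (
        [(0, 0, Phenotype.IMMATURE_DC)] * 6
        + [(480, 0, Phenotype.IMMATURE_DC)] * 6
        + [(240, 0, Phenotype.IMMATURE_DC)]
    )
    return make_map(spec, node_id="bridge")


@pytest.fixture
def twenty_cell_map():
    """Hand-enumerable 20-cell node.

    7 DCs: 6 coincident at the origin (3 mature) forming one cluster at
    R=250/D=5, plus 1 isolated immature DC 10,000 px away; 8 T cells and
    5 OTHER cells far from everything.
    """
    spec = (
        [(0, 0, Phenotype.MATURE_DC)] * 3
        + [(0, 0, Phenotype.IMMATURE_DC)] * 3
        + [(10_000, 0, Phenotype.IMMATURE_DC)]
        + [(5_000, 5_000, Phenotype.T_CELL)] * 8
        + [(5_000, 8_000, Phenotype.OTHER)] * 5
    )
    return make_map(spec, node_id="fixture20")
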