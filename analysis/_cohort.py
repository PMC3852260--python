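"""Shared cohort location for the analysis drivers.

Cell-map CSVs are bulky generated artifacts, so they live under
scratch/cohort/ and are regenerated deterministically (fixed seed) when
absent; only small derived tables go to results/.
"""

from pathlib import Path

import dcspatial as dc

SEED = 20130
REPO = Path(__file__).resolve().parents[1]
COHORT_DIR = REPO / "scratch" / "cohort"
RESULTS = REPO / "results"


def ensure_cohort(force: bool = False) -> Path:
    """Write the 90-node three-group cohort to scratch/cohort/ if missing."""
    marker = COHORT_DIR / "metadata.csv"
    if marker.exists() and not force:
        return COHORT_DIR
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    cohort, truths = dc.generate_cohort(dc.three_group_cohort(n_nodes=30, seed=SEED))
    for cell_map, md in cohort:
        dc.write_cell_map(cell_map, COHORT_DIR / f"{md.node_id}.csv")
    dc.write_metadata([md for _, md in cohort], marker)
    import pandas as pd

    pd.DataFrame(
        [
            {
                "node_id": nid,
                "true_clustered_fraction": t.true_clustered_fraction,
                "n_planted_dcs": len(t.planted_dc_ids()),
                "n_dcs": len(t.dc_source),
            }
            for nid, t in truths.items()
        ]
    ).to_csv(COHORT_DIR / "ground_truth.csv", index=False)
    return COHORT_DIR
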