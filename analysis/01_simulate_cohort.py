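"""Simulate the study cohort: healthy-like, tumor-free-like and
tumor-involved-like lymph nodes (30 each), written as cell-map CSVs with
cohort metadata and ground truth.

Cell maps land in scratch/cohort/ (bulky, regenerable); the per-node
ground-truth summary is copied to results/cohort_ground_truth.csv.
"""

import shutil

import pandas as pd

import dcspatial as dc
from _cohort import COHORT_DIR, RESULTS, ensure_cohort


def main() -> None:
    ensure_cohort(force=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    shutil.copy(COHORT_DIR / "ground_truth.csv", RESULTS / "cohort_ground_truth.csv")

    metadata = dc.read_metadata(COHORT_DIR / "metadata.csv")
    truth = pd.read_csv(COHORT_DIR / "ground_truth.csv")
    print(f"simulated {len(metadata)} nodes into {COHORT_DIR}")
    print(pd.Series([md.group.value for md in metadata]).value_counts().to_string())
    print(
        "median true clustered fraction by group:\n",
        truth.assign(group=truth.node_id.str.rsplit("_", n=1).str[0])
        .groupby("group")
        .true_clustered_fraction.median()
        .round(3)
        .to_string(),
    )


if __name__ == "__main__":
    main()
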