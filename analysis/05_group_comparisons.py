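"""Between-group comparisons of every node metric (healthy-like vs
tumor-free-like vs tumor-involved-like), Mann-Whitney tests, and the
clustering-vs-maturity linear association within the tumor-involved group.

Input:  results/node_metrics.csv   Output: results/group_comparisons.csv
"""

import itertools
from pathlib import Path

import pandas as pd

import dcspatial as dc

ROOT = Path(__file__).resolve().parents[1] / "results"
METRICS = [
    "pct_dcs",
    "pct_mature_dcs",
    "pct_clustered_dcs",
    "rel_cluster_count_e3",
    "mean_cluster_size",
    "pct_mature_clustered",
    "pct_t_cells",
]


def main() -> None:
    df = pd.read_csv(ROOT / "node_metrics.csv")
    rows = []
    for metric in METRICS:
        for ga, gb in itertools.combinations(["HLN", "NSLN_NEG", "NSLN_POS"], 2):
            a = df.loc[df.group == ga, metric].dropna().tolist()
            b = df.loc[df.group == gb, metric].dropna().tolist()
            u, p = dc.compare_groups(a, b)
            rows.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "median_a": pd.Series(a).median(),
                    "median_b": pd.Series(b).median(),
                    "U": u,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "group_comparisons.csv", index=False)
    print(out.round(4).to_string(index=False))

    sub = df[df.group == "NSLN_POS"].dropna(subset=["pct_clustered_dcs", "pct_mature_dcs"])
    slope, r2, p = dc.linear_assoc(sub.pct_clustered_dcs, sub.pct_mature_dcs)
    print(
        f"\n%clustered vs %mature in NSLN+-like (n={len(sub)}): "
        f"slope={slope:.3f}, R^2={r2:.3f}, p={p:.3f}"
    )


if __name__ == "__main__":
    main()
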