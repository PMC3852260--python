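# dcspatial

Spatial analysis of dendritic-cell (DC) organization in lymph-node
sections, for immunologists and computational pathologists working with
cell-coordinate output of IHC image classifiers (GemIdent-style CSVs:
one row per cell with x, y in pixels and a phenotype derived from
CD1a/CD83/CD3/CD20/pan-cytokeratin/hematoxylin staining).

The package quantifies how DCs aggregate, how aggregation relates to DC
maturity and to nearby T cells, and whether a patient's degree of DC
clustering stratifies disease-free survival — the chain of analyses
through which DC spatial organization in tumor-draining lymph nodes has
been linked to breast-cancer outcome.

## The method

**Density-based clustering (DBC).** For the DC point set *S* (every
CD1a+ and/or CD83+ cell), each DC *p* with at least *D* DCs inside the
closed disc *C(p)* of radius *R* (self included) labels all of
*S ∩ C(p)* as one provisional cluster; provisional clusters sharing any
member merge transitively; unlabeled DCs are noise. Defaults *R* = 250 px,
*D* = 5. Unlike DBSCAN there is no border-point single-assignment — any
overlap merges. `dbc_cluster` (k-d tree + union-find) scales to tens of
thousands of DCs; `dbc_oracle` re-derives the partition quadratically as
an independent reference.

**Per-node metrics.** %DCs and %T cells (of T + DC + hematoxylin-only
cells), %mature DCs (CD83+ of all DCs), %clustered DCs, relative cluster
count (clusters per DC, reported ×10⁻³), mean cluster size, and %mature
of clustered DCs.

**DC–T co-localization.** A T cell within 100 px of its nearest DC is
associated with that DC (`NEAREST`; an `ALL_WITHIN` multi-counting mode
is also provided). Mean per-DC T-cell counts are compared between
clustered and unclustered DCs.

**Cohort statistics.** Mann–Whitney U (inter-group), Wilcoxon
signed-rank (intra-group), OLS for the clustering–maturity association,
and median-split Kaplan–Meier / log-rank survival analysis after an
eligibility filter (≥5 years of follow-up unless relapsed earlier, no
concurrent cancer, %DCs inside the cohort's center 90% range).

**Synthetic nodes.** Because no patient coordinate data are public, a
generator plants hard-separated Gaussian DC aggregates over Poisson
background cells with ground truth (aggregate membership, T-cell
enrichment source, true clustered fraction) and can link simulated
survival to the true clustered fraction. See `docs/methods.md`.

## Worked example

```python
import dcspatial as dc

cm, truth = dc.generate_node(dc.hln_like(seed=0), node_id="demo")
assignment = dc.dbc_cluster(cm)                     # R=250, D=5
m = dc.compute_node_metrics(cm, assignment)
print(m.pct_clustered_dcs, m.mean_cluster_size, m.pct_mature_dcs)
```

The full analysis is the numbered scripts in `analysis/` (tables land in
`results/`, bulky simulated cell maps in `scratch/`). On the default
90-node cohort, `02_cluster_and_metrics.py` prints:

```
group medians:
          pct_dcs  pct_mature_dcs  pct_clustered_dcs  rel_cluster_count_e3  mean_cluster_size  pct_mature_clustered
HLN          9.37           89.73              94.33                  3.85             245.00                 89.95
NSLN_NEG     8.50           34.50              89.27                  8.73             101.75                 32.28
NSLN_POS     6.92           35.93              71.47                 12.61              57.00                 30.52
```

i.e. the healthy-like group (HLN) shows fewer but larger, denser and more
mature DC clusters than the tumor-free (NSLN_NEG) and tumor-involved
(NSLN_POS) groups, with clustering lowest in tumor-involved nodes.
`06_survival_analysis.py` filters a simulated 40-patient tumor-involved
cohort to 35 eligible patients, median-splits them on %clustered DCs and
prints `log-rank chi^2=14.079, p=0.0002` with Kaplan–Meier median
survival 6.02 years in the LOW stratum and not reached in HIGH — the
high-clustering group relapses later by construction of the simulated
hazard. `04_calibrate_params.py` re-runs the (R, D) grid search against
annotated synthetic training nodes; on tight well-separated aggregates
many grid points tie near F1 ≈ 0.999 and the tie rule selects the
smallest radius.

A CLI mirrors the pipeline (`dcspatial cluster|metrics|coloc|calibrate|compare|survive|simulate --help`).

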