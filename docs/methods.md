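# Methods

## Clustering model

The DC partition is defined directly on the point set, not through a
fitted density. For every DC *p*, n(*p*) counts DCs at Euclidean
distance ≤ *R* from *p*, **including *p* itself** — *p* is geometrically
inside its own disc — so five coincident DCs satisfy n(*p*) = 5 ≥ *D* at
the defaults and form a cluster, while four do not. The disc boundary is
inclusive (distance exactly *R* counts), which keeps tests exact and
avoids floating-point exclusion of on-circle points. Both conventions
are deliberate choices where the verbal algorithm is ambiguous; they are
encoded once in `dbc_cluster` and mirrored by the oracle.

Merging is transitive closure: the fast path runs union-find over the
members of every core disc, the oracle builds the provisional-set
intersection graph and takes connected components. Cluster labels are
canonical — each final cluster is keyed by its smallest member cell_id
and clusters are renumbered 0..k−1 in that order — so output is
invariant to input row permutation.

Only DCs enter the point set. T, B, tumor and hematoxylin-only cells
never influence the partition; they matter only for the metric
denominators and co-localization.

Defaults *R* = 250 px and *D* = 5 are the published operating point of
the original training-slide calibration; `calibration.grid_search`
re-derives a parameter choice on annotated data using mean per-DC
clustered-label F1 (ties → smaller *R*, then smaller *D*). F1 was chosen
over region-overlap criteria because it works at the same granularity as
the algorithm's output and needs no cluster-shape reconstruction. On
clean, well-separated synthetic aggregates the F1 surface is nearly flat
across the default grid, so the selected radius can fall below 250 px;
the grid table is always emitted so such plateaus are visible.

## Metrics

Cell-count normalization throughout (no area normalization; the source
images carry no physical pixel size, so all distances stay in pixels).
The %DC / %T denominator is T + DC + OTHER, excluding tumor and B cells;
`include_all_non_tumor=True` widens it. Whether the original denominator
included B or tumor cells is not fully determinable (serial sections
carried different antibody panels); the narrow reading of "all T cells,
DCs, and other hematoxylin-stained cells" is the default. Zero
denominators yield missing values (`None`), never 0 — a node with no
clusters contributes no mean-cluster-size observation rather than a 0,
and group summaries drop such nodes pairwise. Mean cluster size averages
within a node; group-level summaries average node means, not pooled
clusters.

## Co-localization

100 px approximates a DC's diameter including dendrites in the source
imagery; the model considers physical-contact potential only (no soluble
factors). `NEAREST` follows the stated assignment rule (each T cell to
its nearest DC if within the radius, ties to the smaller cell_id);
`ALL_WITHIN` is kept because "T cells surrounding a DC" is also
compatible with multi-counting, and which counting produced the
published per-DC means is not stated. The two modes differ structurally:
under `NEAREST`, T cells inside a dense aggregate are split among its
DCs, so even without enrichment the per-DC mean is lower for clustered
than isolated DCs; under `ALL_WITHIN` the expected per-DC count is the
ambient T intensity × πr² regardless of clustering. Sign-balance
(null) checks therefore use `ALL_WITHIN`; enrichment detection holds in
both modes.

## Statistics

Mann–Whitney: exact null when min(n) ≤ 8 and the pooled sample is
tie-free, otherwise the tie-corrected normal approximation *without*
continuity correction (so identical samples give p = 1 exactly).
Wilcoxon signed-rank: zeros dropped, exact null up to n = 15 after zero
removal. Both two-sided, α = 0.05. The median split is rank-based with
stable order; odd cohorts put the middle observation in LOW (the
original cohorts were even, so this choice is inert there). The
eligibility filter applies the follow-up and concurrent-cancer rules
first and computes the 5th/95th %DC percentiles (linear interpolation)
on those survivors, excluding the tails strictly; the ordering of the
two stages is not specified in the source description and is fixed here
as stated. Kaplan–Meier and log-rank come from lifelines; a
hand-tabulated two-event-time example pins the statistic in the tests.

## Synthetic generator

`generate_node` emulates classifier output, not images: planted
aggregates are a hard-separated Thomas-like process (centers ≥ 4σ apart
and from the border, members Gaussian(σ), Poisson counts), everything
else homogeneous Poisson. The separation makes planted membership
unambiguous for F1 scoring — at σ = 60 px essentially every planted DC
lies within 250 px of dense same-aggregate neighbors and background DCs
(≈50 per 10⁸ px²) almost never reach density 5, which is what makes
≈0.99 recovery F1 the expected outcome rather than a tuned one. The
recovery preset (10 aggregates × Poisson(50) DCs, σ = 60, 50 background
DCs, 10,000² px) is the documented recovery condition. Randomness: one
root seed; cohort node *i* uses a stream spawned from (root, *i*), so
cohorts are reproducible independently of generation order.

Group presets encode the qualitative healthy-vs-tumor contrasts —
HLN-like: 4 aggregates × 240 DCs (σ = 120), 60 background, maturity 0.90
in/0.85 out; NSLN−-like: 8 × 100 (σ = 80), 100 background, 0.32/0.55;
NSLN+-like: 8 × 55 (σ = 60), 190 background, 0.31/0.50, reduced T
enrichment (1.2 vs 2.0 extra T per aggregated DC). These are implementer
choices that reproduce orderings (clustered fraction ≈0.94/0.89/0.70,
relative cluster counts ≈4/9/13 ×10⁻³, cluster sizes ≈240/100/55), never
estimates of the real cohort — fitting them to published medians would
be circular with no underlying data released.

The survival cohort mixes a low-clustering (fraction ≈0.42) and a
high-clustering (≈0.81) tumor-involved variant, because within one
preset the realized clustered fraction is a Poisson ratio with sd ≈0.02
— far too narrow for a median split to separate anything. Disease-free
time is exponential with rate 0.6·exp(−4.5·fraction) per year, censored
administratively at 12 years, with 5% early loss to follow-up and 3%
concurrent-cancer flags to exercise the eligibility filter. The hazard
parameters were fixed by a design-time power analysis targeting ≈0.9
power for the 40-patient median-split log-rank, a strength consistent
with the large stratification effect the original 19-patient cohort
showed.

### What the generator does not emulate

Tissue architecture (follicles, sinuses, irregular section outlines),
anisotropic or contiguous aggregates, classifier error (mislabeled
phenotypes, split/merged nuclei), spatially varying background
intensity, and any dependence structure between maturity and position
beyond the in/out-of-aggregate rates. Passing recovery and contrast
tests therefore shows the pipeline is correct and well-calibrated on its
stated model, not that the biological findings would replicate on real
slides. One visible artifact: because background DCs have a different
maturity rate than aggregated ones, %clustered and %mature are weakly
negatively coupled across simulated NSLN+-like nodes, whereas the
original cohort reported no association (R² = 0.04); the regression
driver surfaces this rather than hiding it.

## Problem sizes

Defaults throughout were sized for a laptop-class single core: recovery
and enrichment checks run 50–100 nodes of ~550 DCs, oracle equivalence
100 instances up to 1,000 DCs, null calibrations 500–1,000 replicates,
and the power study 100–200 replicates of 40-patient cohorts; all
complete in a few minutes total. Larger replications only sharpen the
same estimates.
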