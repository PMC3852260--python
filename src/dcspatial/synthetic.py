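"""Synthetic lymph-node cell maps with ground truth.

No coordinate data from the original patient cohort were ever deposited,
so recovery and calibration testing runs on simulated nodes that emulate
the structure of classifier output from stained sections:

- DC aggregates planted as a hard-separated Thomas-like process: cluster
  centers rejection-sampled at least 4 sigma apart (and from the border)
  so planted identity is unambiguous; member DCs Gaussian about the
  center with a Poisson member count.
- Isolated background DCs, T cells and hematoxylin-only (OTHER) cells as
  homogeneous Poisson processes over the extent.
- Maturity labels Bernoulli, with a different rate inside aggregates than
  in the background.
- T-cell enrichment near aggregated DCs: per planted DC, a Poisson number
  of extra T cells placed uniformly in its 100-pixel influence disc.
- Optional cohort generation links each patient's disease-free survival
  to the node's true clustered fraction through an exponential
  proportional-hazards model with administrative censoring.

Every draw is deterministic given the seed; per-node streams in a cohort
are derived by seed-sequence spawning from (root seed, node index), so a
cohort is reproducible regardless of generation order.

Preset configurations mimic the qualitative contrasts between healthy
(HLN-like) and tumor-draining (NSLN-like) nodes — larger, denser, more
mature aggregates in healthy nodes — without claiming to estimate any
real cohort's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Cell, CellMap, NodeGroup, NodeMetadata, Phenotype

__all__ = [
    "BACKGROUND",
    "SynthConfig",
    "GroundTruth",
    "GroupSpec",
    "CohortConfig",
    "generate_node",
    "generate_cohort",
    "recovery_preset",
    "hln_like",
    "nsln_neg_like",
    "nsln_pos_like",
    "three_group_cohort",
    "survival_cohort",
]

#: Ground-truth label for cells not generated by any planted aggregate.
BACKGROUND = -1

_ENRICH_RADIUS = 100.0  # px; matches the co-localization influence radius


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one synthetic node.

    Defaults are the documented recovery preset: 10 well-separated
    aggregates of ~50 DCs (sigma 60 px) plus 50 isolated DCs on a
    10,000 x 10,000 px section.
    """

    extent: tuple[float, float] = (10_000.0, 10_000.0)
    n_planted_clusters: int = 10
    cluster_sigma: float = 60.0
    dcs_per_cluster: float = 50.0  # Poisson mean
    background_dc_rate: float = 50.0  # expected isolated DCs
    p_mature_in_cluster: float = 0.5
    p_mature_background: float = 0.3
    t_background_rate: float = 2_000.0  # expected T cells over the extent
    t_enrichment_per_clustered_dc: float = 2.0  # mean extra T per planted DC
    other_cell_rate: float = 3_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_mature_in_cluster", "p_mature_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "dcs_per_cluster",
            "background_dc_rate",
            "t_background_rate",
            "t_enrichment_per_clustered_dc",
            "other_cell_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_planted_clusters < 0:
            raise ValueError("n_planted_clusters must be >= 0")
        if self.n_planted_clusters > 0 and self.cluster_sigma <= 0:
            raise ValueError("cluster_sigma must be > 0")


@dataclass
class GroundTruth:
    """True generative labels for one synthetic node.

    ``dc_source[cell_id]`` is the planted aggregate index or
    :data:`BACKGROUND`; ``t_source[cell_id]`` is the planted DC a T cell
    was enriched around, or :data:`BACKGROUND` for ambient T cells.
    ``true_clustered_fraction`` is the realized planted-DC share of all
    DCs (None when the node has no DCs).
    """

    node_id: str
    dc_source: dict[int, int] = field(default_factory=dict)
    t_source: dict[int, int] = field(default_factory=dict)
    true_clustered_fraction: float | None = None

    def planted_dc_ids(self) -> set[int]:
        return {cid for cid, src in self.dc_source.items() if src != BACKGROUND}


def _sample_centers(
    rng: np.random.Generator, config: SynthConfig, max_attempts: int = 20_000
) -> np.ndarray:
    """Rejection-sample aggregate centers >= 4 sigma apart and from the border."""
    k = config.n_planted_clusters
    if k == 0:
        return np.empty((0, 2))
    margin = 4.0 * config.cluster_sigma
    w, h = config.extent
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("extent too small for the requested cluster_sigma margin")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < k:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place well-separated cluster centers; extent too small "
                f"for {k} clusters at sigma {config.cluster_sigma}"
            )
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(cand - c)) >= margin for c in centers):
            centers.append(cand)
    return np.array(centers)


def generate_node(config: SynthConfig, node_id: str = "synthetic") -> tuple[CellMap, GroundTruth]:
    """Draw one synthetic node. Deterministic given ``config.seed``.

    Cell ids are sequential in emission order: planted DCs (aggregate by
    aggregate), background DCs, ambient T cells, enrichment T cells,
    OTHER cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    w, h = config.extent
    truth = GroundTruth(node_id=node_id)

    # Coordinate blocks are accumulated vectorized, cells materialized once.
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    phenos: list[Phenotype] = []

    def emit_block(xy: np.ndarray, phenotypes: list[Phenotype]) -> np.ndarray:
        """Append a block; returns the cell_ids assigned to it."""
        start = len(phenos)
        xs.append(np.clip(xy[:, 0], 0, w))
        ys.append(np.clip(xy[:, 1], 0, h))
        phenos.extend(phenotypes)
        return np.arange(start, len(phenos))

    def dc_phenotypes(mature_mask: np.ndarray) -> list[Phenotype]:
        return [Phenotype.MATURE_DC if m else Phenotype.IMMATURE_DC for m in mature_mask]

    # Planted DC aggregates.
    centers = _sample_centers(rng, config)
    planted_ids: list[np.ndarray] = []
    planted_xy: list[np.ndarray] = []
    for ci, center in enumerate(centers):
        m = rng.poisson(config.dcs_per_cluster)
        xy = center + rng.normal(0.0, config.cluster_sigma, size=(m, 2))
        mature = rng.random(m) < config.p_mature_in_cluster
        ids = emit_block(xy, dc_phenotypes(mature))
        truth.dc_source.update({int(cid): ci for cid in ids})
        planted_ids.append(ids)
        planted_xy.append(np.column_stack([np.clip(xy[:, 0], 0, w), np.clip(xy[:, 1], 0, h)]))

    # Isolated background DCs.
    n_bg = rng.poisson(config.background_dc_rate)
    bg_xy = rng.uniform([0, 0], [w, h], size=(n_bg, 2))
    ids = emit_block(bg_xy, dc_phenotypes(rng.random(n_bg) < config.p_mature_background))
    truth.dc_source.update({int(cid): BACKGROUND for cid in ids})

    # Ambient T cells.
    n_t = rng.poisson(config.t_background_rate)
    ids = emit_block(rng.uniform([0, 0], [w, h], size=(n_t, 2)), [Phenotype.T_CELL] * n_t)
    truth.t_source.update({int(cid): BACKGROUND for cid in ids})

    # Enrichment T cells in the influence disc of each planted DC.
    if config.t_enrichment_per_clustered_dc > 0 and planted_ids:
        all_planted_ids = np.concatenate(planted_ids)
        all_planted_xy = np.vstack(planted_xy)
        counts = rng.poisson(config.t_enrichment_per_clustered_dc, size=len(all_planted_ids))
        total = int(counts.sum())
        src = np.repeat(all_planted_ids, counts)
        anchors = np.repeat(all_planted_xy, counts, axis=0)
        r = _ENRICH_RADIUS * np.sqrt(rng.random(total))
        theta = rng.uniform(0, 2 * np.pi, size=total)
        xy = anchors + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        ids = emit_block(xy, [Phenotype.T_CELL] * total)
        truth.t_source.update({int(cid): int(s) for cid, s in zip(ids, src)})

    # Hematoxylin-only cells.
    n_other = rng.poisson(config.other_cell_rate)
    emit_block(rng.uniform([0, 0], [w, h], size=(n_other, 2)), [Phenotype.OTHER] * n_other)

    x_all = np.concatenate(xs) if xs else np.empty(0)
    y_all = np.concatenate(ys) if ys else np.empty(0)
    cells = [
        Cell(i, float(x), float(y), p) for i, (x, y, p) in enumerate(zip(x_all, y_all, phenos))
    ]
    n_planted = sum(len(ids) for ids in planted_ids)
    n_dcs = n_planted + n_bg
    truth.true_clustered_fraction = (n_planted / n_dcs) if n_dcs else None
    return CellMap(node_id=node_id, cells=cells, extent=config.extent), truth


# ---------------------------------------------------------------------------
# Group presets: qualitative healthy-vs-tumor-draining contrasts.
# ---------------------------------------------------------------------------


def recovery_preset(seed: int = 0) -> SynthConfig:
    """The documented parameter-recovery preset (also the default config)."""
    return SynthConfig(seed=seed)


def hln_like(seed: int = 0) -> SynthConfig:
    """Healthy-node preset: few, large, dense, predominantly mature aggregates."""
    return SynthConfig(
        n_planted_clusters=4,
        cluster_sigma=120.0,
        dcs_per_cluster=240.0,
        background_dc_rate=60.0,
        p_mature_in_cluster=0.90,
        p_mature_background=0.85,
        t_background_rate=3_000.0,
        t_enrichment_per_clustered_dc=2.0,
        other_cell_rate=5_000.0,
        seed=seed,
    )


def nsln_neg_like(seed: int = 0) -> SynthConfig:
    """Tumor-free node preset: more numerous but smaller, less mature aggregates."""
    return SynthConfig(
        n_planted_clusters=8,
        cluster_sigma=80.0,
        dcs_per_cluster=100.0,
        background_dc_rate=100.0,
        p_mature_in_cluster=0.32,
        p_mature_background=0.55,
        t_background_rate=3_000.0,
        t_enrichment_per_clustered_dc=2.0,
        other_cell_rate=5_000.0,
        seed=seed,
    )


def nsln_pos_like(seed: int = 0) -> SynthConfig:
    """Tumor-involved node preset: small sparse aggregates, many isolated DCs,
    reduced T-cell enrichment."""
    return SynthConfig(
        n_planted_clusters=8,
        cluster_sigma=60.0,
        dcs_per_cluster=55.0,
        background_dc_rate=190.0,
        p_mature_in_cluster=0.31,
        p_mature_background=0.50,
        t_background_rate=3_000.0,
        t_enrichment_per_clustered_dc=1.2,
        other_cell_rate=5_000.0,
        seed=seed,
    )


PRESETS = {"hln": hln_like, "nsln-neg": nsln_neg_like, "nsln-pos": nsln_pos_like}


# ---------------------------------------------------------------------------
# Cohort generation with survival linkage.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One cohort stratum: a node-group label, its generative preset, and size."""

    name: str
    group: NodeGroup
    config: SynthConfig
    n_nodes: int


@dataclass(frozen=True)
class CohortConfig:
    """A synthetic patient cohort (one node per patient).

    Disease-free time is exponential with per-year rate
    ``baseline_hazard * exp(-log_hazard_coef * true_clustered_fraction)``,
    so a positive coefficient makes higher DC clustering protective.
    Follow-up is administratively censored at ``censor_years``; a fraction
    ``p_early_censor`` of patients is instead lost to follow-up at a
    uniform time in (1, censor_years), and a fraction ``p_concurrent``
    carries a concurrent-cancer flag — both exercise the survival
    eligibility filter.
    """

    groups: tuple[GroupSpec, ...]
    baseline_hazard: float = 0.6
    log_hazard_coef: float = 4.5
    censor_years: float = 12.0
    p_early_censor: float = 0.05
    p_concurrent: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_years <= 0:
            raise ValueError("censor_years must be > 0")


def three_group_cohort(n_nodes: int = 30, seed: int = 0) -> CohortConfig:
    """HLN-like / NSLN--like / NSLN+-like cohort for group comparisons."""
    return CohortConfig(
        groups=(
            GroupSpec("HLN", NodeGroup.HLN, hln_like(), n_nodes),
            GroupSpec("NSLNneg", NodeGroup.NSLN_NEG, nsln_neg_like(), n_nodes),
            GroupSpec("NSLNpos", NodeGroup.NSLN_POS, nsln_pos_like(), n_nodes),
        ),
        seed=seed,
    )


def survival_cohort(n_patients: int = 40, seed: int = 0) -> CohortConfig:
    """Tumor-involved cohort with bimodal clustering for survival stratification.

    Half the patients carry a low-clustering node (4 aggregates over a
    large isolated-DC background, true clustered fraction ~0.42), half a
    high-clustering node (~0.81), emulating the within-group spread the
    median split stratifies on. Ancillary cell rates are reduced since
    they do not enter the survival model.
    """
    low = replace(
        nsln_pos_like(),
        n_planted_clusters=4,
        background_dc_rate=300.0,
        t_background_rate=1_000.0,
        other_cell_rate=1_000.0,
    )
    high = replace(
        nsln_pos_like(),
        n_planted_clusters=8,
        background_dc_rate=100.0,
        t_background_rate=1_000.0,
        other_cell_rate=1_000.0,
    )
    n_low = n_patients // 2
    return CohortConfig(
        groups=(
            GroupSpec("NSLNpos_low", NodeGroup.NSLN_POS, low, n_low),
            GroupSpec("NSLNpos_high", NodeGroup.NSLN_POS, high, n_patients - n_low),
        ),
        seed=seed,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[tuple[CellMap, NodeMetadata]], dict[str, GroundTruth]]:
    """Generate one node per patient plus linked survival metadata.

    Returns the cohort in group order and a ground-truth dict keyed by
    node_id. Reproducible: node ``i`` uses a stream spawned from
    ``(config.seed, i)`` regardless of generation order.
    """
    cohort: list[tuple[CellMap, NodeMetadata]] = []
    truths: dict[str, GroundTruth] = {}
    index = 0
    for spec in config.groups:
        for j in range(spec.n_nodes):
            ss = np.random.SeedSequence((config.seed, index))
            node_seed, meta_entropy = (int(s) for s in ss.generate_state(2) >> 1)
            node_id = f"{spec.name}_{j:03d}"
            node_cfg = replace(spec.config, seed=node_seed)
            cell_map, truth = generate_node(node_cfg, node_id=node_id)
            truths[node_id] = truth

            rng = np.random.default_rng(meta_entropy)
            frac = truth.true_clustered_fraction or 0.0
            rate = config.baseline_hazard * np.exp(-config.log_hazard_coef * frac)
            t_relapse = rng.exponential(1.0 / rate)
            if rng.random() < config.p_early_censor:
                t_censor = rng.uniform(1.0, config.censor_years)
            else:
                t_censor = config.censor_years
            event = t_relapse <= t_censor
            cohort.append(
                (
                    cell_map,
                    NodeMetadata(
                        node_id=node_id,
                        group=spec.group,
                        patient_id=f"P{index:04d}",
                        followup_years=float(min(t_relapse, t_censor)),
                        relapse_event=bool(event),
                        concurrent_cancer=bool(rng.random() < config.p_concurrent),
                    ),
                )
            )
            index += 1
    return cohort, truths
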