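from dataclasses import replace

import numpy as np
import pytest

from dcspatial import (
    BACKGROUND,
    Phenotype,
    SplitLabel,
    SurvivalRecord,
    SynthConfig,
    dbc_cluster,
    generate_cohort,
    generate_node,
    hln_like,
    km_logrank,
    median_split,
    nsln_pos_like,
    recovery_preset,
    survival_cohort,
    three_group_cohort,
)


def light(config, **overrides):
    """Preset with ancillary cell populations switched off, for speed."""
    return replace(
        config, t_background_rate=0.0, other_cell_rate=0.0,
        t_enrichment_per_clustered_dc=0.0, **overrides,
    )


class TestGenerateNode:
    def test_empty_configuration_yields_no_dcs(self):
        cfg = light(SynthConfig(n_planted_clusters=0, background_dc_rate=0.0, seed=1))
        cm, truth = generate_node(cfg)
        assert cm.dcs() == []
        assert truth.true_clustered_fraction is None

    def test_same_seed_is_deterministic(self):
        cfg = recovery_preset(seed=9)
        cm1, t1 = generate_node(cfg)
        cm2, t2 = generate_node(cfg)
        assert cm1 == cm2
        assert t1.dc_source == t2.dc_source and t1.t_source == t2.t_source

    def test_ground_truth_consistent_with_cell_map(self):
        cm, truth = generate_node(recovery_preset(seed=2))
        dc_ids = {c.cell_id for c in cm.dcs()}
        t_ids = {c.cell_id for c in cm.cells if c.phenotype is Phenotype.T_CELL}
        assert set(truth.dc_source) == dc_ids
        assert set(truth.t_source) == t_ids
        planted = truth.planted_dc_ids()
        assert truth.true_clustered_fraction == pytest.approx(len(planted) / len(dc_ids))

    def test_planted_count_matches_poisson_mean(self):
        # 200 seeds at 10 clusters x Poisson(50): mean planted DCs within
        # 3 standard errors of 500.
        counts = []
        for s in range(200):
            _, truth = generate_node(light(recovery_preset(), seed=s))
            counts.append(len(truth.planted_dc_ids()))
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 500) < 3 * se

    def test_centers_respect_separation(self):
        # Planted aggregates never overlap: any two planted DCs from
        # different aggregates are farther apart than 2 sigma on average;
        # check the center-separation invariant through aggregate means.
        cm, truth = generate_node(light(recovery_preset(), seed=6))
        by_cluster = {}
        pos = {c.cell_id: (c.x, c.y) for c in cm.dcs()}
        for cid, src in truth.dc_source.items():
            if src != BACKGROUND:
                by_cluster.setdefault(src, []).append(pos[cid])
        centers = [np.mean(v, axis=0) for v in by_cluster.values()]
        sigma = 60.0
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                assert np.hypot(*(centers[i] - centers[j])) > 3 * sigma

    def test_extent_too_small_raises(self):
        cfg = SynthConfig(extent=(500, 500), n_planted_clusters=20, cluster_sigma=60)
        with pytest.raises(ValueError):
            generate_node(cfg)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(p_mature_in_cluster=1.5)


class TestGenerateCohort:
    def test_reproducible_given_seed(self):
        cfg = survival_cohort(n_patients=6, seed=3)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        assert [md for _, md in c1] == [md for _, md in c2]
        assert all(t1[k].dc_source == t2[k].dc_source for k in t1)

    def test_exponential_median_closed_form_when_no_effect(self):
        # coef = 0: disease-free times are exponential(baseline), median ln2/rate.
        cfg = replace(
            survival_cohort(n_patients=300, seed=8),
            log_hazard_coef=0.0,
            baseline_hazard=0.5,
            censor_years=1e6,
            p_early_censor=0.0,
        )
        empty = SynthConfig(n_planted_clusters=0, background_dc_rate=0.0,
                            t_background_rate=0.0, other_cell_rate=0.0)
        cfg = replace(cfg, groups=tuple(replace(g, config=empty) for g in cfg.groups))
        cohort, _ = generate_cohort(cfg)
        times = [md.followup_years for _, md in cohort]
        assert np.median(times) == pytest.approx(np.log(2) / 0.5, rel=0.2)

    def test_protective_coefficient_gives_longer_high_stratum_survival(self):
        wins = 0
        for rep in range(10):
            cfg = survival_cohort(n_patients=30, seed=100 + rep)
            cohort, truths = generate_cohort(cfg)
            recs = [
                SurvivalRecord(
                    md.patient_id,
                    md.followup_years,
                    md.relapse_event,
                    truths[cm.node_id].true_clustered_fraction,
                )
                for cm, md in cohort
            ]
            labels = median_split([r.covariate for r in recs])
            lo = [r.time for r, l in zip(recs, labels) if l is SplitLabel.LOW]
            hi = [r.time for r, l in zip(recs, labels) if l is SplitLabel.HIGH]
            wins += np.mean(hi) > np.mean(lo)
        assert wins >= 9

    def test_metadata_exercises_eligibility_filter(self):
        cohort, _ = generate_cohort(survival_cohort(n_patients=200, seed=12))
        assert any(md.relapse_event for _, md in cohort)
        assert any(not md.relapse_event for _, md in cohort)
        assert any(md.concurrent_cancer for _, md in cohort)

    def test_invalid_hazard_rejected(self):
        with pytest.raises(ValueError):
            replace(survival_cohort(), baseline_hazard=0.0)


class TestPresetContrasts:
    def test_recovery_preset_clusters_are_recovered(self):
        cm, truth = generate_node(recovery_preset(seed=21))
        a = dbc_cluster(cm)
        planted = truth.planted_dc_ids()
        overlap = len(a.clustered_ids() & planted) / len(planted)
        assert overlap > 0.95

    def test_group_presets_order_clustering(self):
        # Healthy-like nodes cluster more than tumor-involved-like nodes.
        fr_h = [generate_node(replace(hln_like(), seed=s))[1].true_clustered_fraction
                for s in range(5)]
        fr_p = [generate_node(replace(nsln_pos_like(), seed=s))[1].true_clustered_fraction
                for s in range(5)]
        assert min(fr_h) > max(fr_p)

    def test_three_group_cohort_layout(self):
        cohort, truths = generate_cohort(three_group_cohort(n_nodes=2, seed=1))
        assert len(cohort) == 6
        assert len(truths) == 6
        groups = [md.group.value for _, md in cohort]
        assert groups == ["HLN"] * 2 + ["NSLN_NEG"] * 2 + ["NSLN_POS"] * 2
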