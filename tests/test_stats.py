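import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcspatial import (
    NodeGroup,
    NodeMetadata,
    SplitLabel,
    SurvivalRecord,
    compare_groups,
    compare_paired,
    filter_survival_cohort,
    km_logrank,
    linear_assoc,
    median_split,
)
from dcspatial.metrics import NodeMetrics


def make_metrics(pct_dcs):
    return NodeMetrics(
        node_id=f"n{pct_dcs}",
        n_total_cells=100,
        n_dcs=10,
        n_clusters=1,
        pct_dcs=pct_dcs,
        pct_mature_dcs=50.0,
        pct_clustered_dcs=80.0,
        rel_cluster_count=0.1,
        mean_cluster_size=8.0,
        pct_mature_clustered=50.0,
        pct_t_cells=50.0,
    )


def make_meta(node_id, followup=8.0, relapse=False, concurrent=False):
    return NodeMetadata(node_id, NodeGroup.NSLN_POS, f"P_{node_id}", followup, relapse, concurrent)


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        _, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact(self):
        # All 6 rank arrangements equally likely; the observed one is extreme
        # on both sides: p = 2/6.
        u, p = compare_groups([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_single_observation_exact_enumeration(self):
        # U for n=(1,3) is uniform on {0,1,2,3}: observed maximum gives 2*(1/4).
        u, p = compare_groups([5], [1, 2, 3])
        assert u == 3
        assert p == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestComparePaired:
    def test_identical_pairs_degenerate_p_one(self):
        assert compare_paired([1, 2, 3], [1, 2, 3]) == 1.0

    def test_all_positive_differences_exact(self):
        # All 2^3 sign patterns equally likely under the null.
        assert compare_paired([2, 4, 6], [1, 2, 3]) == pytest.approx(2 / 8)

    def test_single_pair_minimal_n(self):
        assert compare_paired([2], [1]) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1, 2], [1])


class TestMedianSplit:
    def test_even_split(self):
        assert median_split([1, 2, 3, 4]) == [
            SplitLabel.LOW,
            SplitLabel.LOW,
            SplitLabel.HIGH,
            SplitLabel.HIGH,
        ]

    def test_odd_middle_goes_low(self):
        assert median_split([3, 1, 2]) == [
            SplitLabel.HIGH,
            SplitLabel.LOW,
            SplitLabel.LOW,
        ]

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([5, 5, 5])

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_balance_and_monotonicity(self, values):
        if len(set(values)) == 1:
            return
        labels = median_split(values)
        n_low = labels.count(SplitLabel.LOW)
        n_high = labels.count(SplitLabel.HIGH)
        assert abs(n_low - n_high) <= 1
        lows = [v for v, l in zip(values, labels) if l is SplitLabel.LOW]
        highs = [v for v, l in zip(values, labels) if l is SplitLabel.HIGH]
        assert max(lows) <= min(highs)


class TestEligibilityFilter:
    def test_twenty_patient_percentile_worked_example(self):
        # pct_dcs 1..20; 5th/95th percentiles by linear interpolation are
        # 1.95 and 19.05, so exactly the two extreme nodes fall outside.
        cohort = [(make_metrics(float(v)), make_meta(str(v))) for v in range(1, 21)]
        kept = filter_survival_cohort(cohort)
        assert len(kept) == 18
        assert {nm.pct_dcs for nm, _ in kept} == set(map(float, range(2, 20)))

    def test_short_followup_without_relapse_excluded(self):
        cohort = [
            (make_metrics(float(v)), make_meta(str(v))) for v in range(1, 21)
        ] + [(make_metrics(10.5), make_meta("short", followup=3.0, relapse=False))]
        assert all(md.node_id != "short" for _, md in filter_survival_cohort(cohort))

    def test_early_relapse_retained(self):
        cohort = [
            (make_metrics(float(v)), make_meta(str(v))) for v in range(1, 21)
        ] + [(make_metrics(10.5), make_meta("early", followup=3.0, relapse=True))]
        assert any(md.node_id == "early" for _, md in filter_survival_cohort(cohort))

    def test_concurrent_cancer_excluded(self):
        cohort = [
            (make_metrics(float(v)), make_meta(str(v))) for v in range(1, 21)
        ] + [(make_metrics(10.5), make_meta("conc", concurrent=True))]
        assert all(md.node_id != "conc" for _, md in filter_survival_cohort(cohort))

    def test_percentiles_computed_after_followup_exclusions(self):
        # The excluded short-followup patient must not shift the percentile gate.
        base = [(make_metrics(float(v)), make_meta(str(v))) for v in range(1, 21)]
        with_extreme = base + [
            (make_metrics(1000.0), make_meta("x", followup=1.0, relapse=False))
        ]
        assert [md.node_id for _, md in filter_survival_cohort(with_extreme)] == [
            md.node_id for _, md in filter_survival_cohort(base)
        ]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            filter_survival_cohort([])


class TestKMLogrank:
    def test_exchangeable_strata_give_chi_square_zero(self):
        records = [
            SurvivalRecord(f"P{i}", t, e, 0.0)
            for i, (t, e) in enumerate([(2, True), (5, False), (2, True), (5, False)])
        ]
        labels = [SplitLabel.LOW, SplitLabel.LOW, SplitLabel.HIGH, SplitLabel.HIGH]
        res = km_logrank(records, labels)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulated_two_event_times(self):
        # Group A: events at t=1 and t=2; group B: censored at t=3, 3.
        # t=1: O-E = 1 - 2/4, V = 1*2*2*3/(4^2*3); t=2: O-E = 1 - 1/3,
        # V = 1*1*2*2/(3^2*2). Chi-square = (7/6)^2 / (1/4 + 2/9) = 2.88235...
        records = [
            SurvivalRecord("a1", 1, True, 0.0),
            SurvivalRecord("a2", 2, True, 0.0),
            SurvivalRecord("b1", 3, False, 0.0),
            SurvivalRecord("b2", 3, False, 0.0),
        ]
        labels = [SplitLabel.LOW, SplitLabel.LOW, SplitLabel.HIGH, SplitLabel.HIGH]
        res = km_logrank(records, labels)
        assert res.chi_square == pytest.approx((7 / 6) ** 2 / (1 / 4 + 2 / 9), rel=1e-6)

    def test_km_curve_shape(self):
        rng = np.random.default_rng(0)
        records = [
            SurvivalRecord(f"P{i}", float(t), bool(e), 0.0)
            for i, (t, e) in enumerate(
                zip(rng.exponential(5, 30), rng.random(30) < 0.7)
            )
        ]
        labels = median_split([float(i) for i in range(30)])
        res = km_logrank(records, labels)
        for curve in (res.curve_low, res.curve_high):
            surv = curve.survival.to_numpy()
            assert surv[0] == 1.0
            assert np.all(np.diff(surv) <= 1e-12)  # non-increasing

    def test_empty_stratum_rejected(self):
        records = [SurvivalRecord("P1", 1.0, True, 0.0)]
        with pytest.raises(ValueError):
            km_logrank(records, [SplitLabel.LOW])


class TestLinearAssoc:
    def test_perfect_fit(self):
        slope, r2, p = linear_assoc([0, 1, 2, 3], [1, 3, 5, 7])
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_symmetric_cancellation(self):
        slope, r2, _ = linear_assoc([0, 1, 2], [0, 1, 0])
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_assoc([1, 1, 1], [1, 2, 3])

    def test_independent_noise_r2_near_reciprocal_n(self):
        # E[R^2] = 1/(n-1) for independent Gaussian noise.
        rng = np.random.default_rng(5)
        n = 40
        r2s = [
            linear_assoc(rng.normal(size=n), rng.normal(size=n))[1] for _ in range(300)
        ]
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.01)


class TestNullUniformity:
    def test_mann_whitney_p_uniform_under_null(self):
        # Continuous null, n=15 per group: the p-value CDF must track the
        # uniform within discreteness at the usual working thresholds.
        rng = np.random.default_rng(17)
        ps = np.array(
            [
                compare_groups(rng.normal(size=15), rng.normal(size=15))[1]
                for _ in range(1500)
            ]
        )
        for alpha in (0.05, 0.1, 0.5):
            assert abs((ps <= alpha).mean() - alpha) < 0.05
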