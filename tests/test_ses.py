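import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chance_qc.genome_io import InputDataError, UsageError
from chance_qc.ses import (
    CATEGORIES,
    TrainingTable,
    allocation_curves,
    detect_amplification_bias,
    detect_input_depth,
    detect_ip_depth,
    divergence_test,
    enrichment_summary,
    ip_strength,
    max_separation,
    q_value,
    scale_factor,
)

counts = st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=40)


class TestAllocationCurves:
    def test_hand_example(self):
        c = allocation_curves([0, 0, 2, 2], [1, 1, 1, 1])
        assert np.allclose(c.p, [0, 0, 0.5, 1])
        assert np.allclose(c.q, [0.25, 0.5, 0.75, 1])

    def test_identical_channels_give_equal_curves(self):
        c = allocation_curves([3, 0, 7, 1], [3, 0, 7, 1])
        assert np.allclose(c.p, c.q)

    def test_two_bin_example(self):
        c = allocation_curves([0, 10], [5, 5])
        assert np.allclose(c.p, [0, 1]) and np.allclose(c.q, [0.5, 1])

    def test_zero_total_rejected(self):
        with pytest.raises(InputDataError):
            allocation_curves([0, 0], [1, 1])

    @given(ip=counts, seed=st.integers(0, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_curves_monotone_and_end_at_one(self, ip, seed):
        rng = np.random.default_rng(seed)
        inp = rng.poisson(3.0, len(ip)) + 1
        ip = np.asarray(ip) + (1 if sum(ip) == 0 else 0)
        c = allocation_curves(ip, inp)
        for curve in (c.p, c.q):
            assert np.all(np.diff(curve) >= -1e-12)
            assert abs(curve[-1] - 1) < 1e-12
            assert np.all((curve >= -1e-12) & (curve <= 1 + 1e-12))


class TestMaxSeparation:
    @pytest.mark.parametrize(
        "ip,inp,expected",
        [
            ([0, 0, 2, 2], [1, 1, 1, 1], (0.5, 0.5)),
            ([0, 10], [5, 5], (0.5, 0.5)),
            ([1, 2, 3], [1, 2, 3], None),  # identical -> d == 0
        ],
    )
    def test_hand_examples(self, ip, inp, expected):
        alpha, d = max_separation(allocation_curves(ip, inp))
        if expected is None:
            assert d == pytest.approx(0.0)
        else:
            assert (alpha, d) == pytest.approx(expected)

    def test_smallest_maximizer_wins_ties(self):
        # q-p = [.25,.25,0,0]: first maximizer at k=1 -> alpha=0.25
        alpha, d = max_separation(allocation_curves([0, 1, 1, 2], [1, 1, 1, 1]))
        gap = allocation_curves([0, 1, 1, 2], [1, 1, 1, 1])
        assert alpha == pytest.approx(0.25) and d == pytest.approx(0.25)

    def test_permutation_invariance(self):
        # tie-free IP counts: the stable genomic tie-break does not engage,
        # so the statistic depends only on the (ip, input) value pairs
        rng = np.random.default_rng(3)
        ip = rng.permutation(300)
        inp = rng.poisson(4, 300)
        perm = rng.permutation(300)
        a1 = max_separation(allocation_curves(ip, inp))
        a2 = max_separation(allocation_curves(ip[perm], inp[perm]))
        assert a1 == pytest.approx(a2)


class TestScaleFactor:
    def test_hand_examples(self):
        assert scale_factor([1, 1, 1, 9], [2, 2, 2, 2], 0.75) == pytest.approx(0.5)
        assert scale_factor([2, 2, 4, 40], [1, 1, 1, 1], 0.75) == pytest.approx(8 / 3)
        assert scale_factor([1, 2, 3], [1, 2, 3], 1.0) == pytest.approx(1.0)

    def test_zero_input_background_advises_depth(self):
        with pytest.raises(InputDataError, match="depth"):
            scale_factor([1, 1, 9], [0, 0, 5], 2 / 3)


class TestEnrichmentSummary:
    def test_hand_example(self):
        res = enrichment_summary([1, 1, 1, 9], [2, 2, 2, 2], 0.75, 0.5, 0.5)
        assert res.pct_genome_enriched == pytest.approx(25.0)
        assert res.pct_signal_reads == pytest.approx(100 * (1 - 0.5 * 8 / 12))

    def test_identical_channels_declared_not_enriched(self):
        res = enrichment_summary([1, 2, 3], [1, 2, 3], 1.0, 0.0, 1.0)
        assert res.pct_genome_enriched == 0.0
        assert res.pct_signal_reads == 0.0

    def test_planted_signal_fraction_recovered(self):
        from chance_qc.fixtures import EnrichmentSpec, gen_binned_pair

        ip, inp = gen_binned_pair(
            EnrichmentSpec(n_bins=50_000, signal_fraction=0.1, signal_fold=10, seed=5)
        )
        curves = allocation_curves(ip, inp)
        alpha, d = max_separation(curves)
        r = scale_factor(ip, inp, alpha)
        res = enrichment_summary(ip, inp, alpha, d, r)
        assert res.pct_genome_enriched == pytest.approx(10.0, abs=2.0)
        # excess reads over background in IP: s(f-1)/(1-s+sf) ~ 47.4%
        assert res.pct_signal_reads == pytest.approx(47.4, abs=5.0)


class TestDivergenceTest:
    def test_null_pair_not_significant(self, null_pair):
        ip, inp = null_pair
        assert divergence_test(ip, inp, n_resamples=99, seed=0) >= 0.05

    def test_strong_enrichment_hits_floor(self, small_pair):
        ip, inp = small_pair
        assert divergence_test(ip, inp, n_resamples=99, seed=0) == pytest.approx(
            1 / 100
        )

    def test_zero_resamples_rejected(self, small_pair):
        with pytest.raises(UsageError):
            divergence_test(*small_pair, n_resamples=0)

    def test_p_never_below_floor(self, small_pair):
        p = divergence_test(*small_pair, n_resamples=19, seed=1)
        assert p >= 1 / 20


@pytest.fixture
def toy_table():
    frame = pd.DataFrame(
        {
            "category": ["histone_normal"] * 4,
            "pair_type": ["Input_Input", "Input_Input", "IP_Input", "IP_Input"],
            "divergence_stat": [0.1, 0.2, 0.3, 0.4],
        }
    )
    return TrainingTable(frame)


class TestQValue:
    def test_hand_counts(self, toy_table):
        assert q_value(0.25, toy_table, "histone_normal") == pytest.approx(0.0)
        assert q_value(0.15, toy_table, "histone_normal") == pytest.approx(1 / 3)

    def test_empty_tail_convention(self, toy_table):
        assert q_value(0.99, toy_table) == 0.0

    def test_empty_category_raises(self, toy_table):
        with pytest.raises(InputDataError, match="tf_cancer"):
            q_value(0.1, toy_table, "tf_cancer")

    def test_nonincreasing_in_d(self, toy_table):
        grid = np.linspace(-1, 1, 41)
        qs = [q_value(d, toy_table, "histone_normal") for d in grid]
        assert all(a >= b for a, b in zip(qs, qs[1:]))


class TestDepthWarnings:
    def test_input_depth_crossing_detected(self):
        c = allocation_curves([1, 1, 1, 1], [0, 0, 4, 4])
        assert detect_input_depth(c)

    def test_no_crossing_no_warning(self):
        assert not detect_input_depth(allocation_curves([0, 0, 2, 2], [1, 1, 1, 1]))
        # equality (identical channels) is not a strict dip
        assert not detect_input_depth(allocation_curves([1, 2, 3], [1, 2, 3]))

    def test_ip_depth_excision(self):
        ip, inp = np.array([0, 0, 0, 6]), np.array([1, 1, 1, 3])
        curves = allocation_curves(ip, inp)
        alpha, _ = max_separation(curves)
        warn, alpha0, rerun = detect_ip_depth(ip, inp, curves, alpha)
        assert warn and alpha0 == pytest.approx(0.75)
        assert rerun is not None and rerun.n_ip == 6

    def test_ip_depth_edge_at_alpha0(self):
        ip, inp = np.array([0, 5, 5, 5]), np.array([1, 1, 1, 1])
        curves = allocation_curves(ip, inp)
        alpha, _ = max_separation(curves)
        warn, alpha0, _ = detect_ip_depth(ip, inp, curves, alpha)
        assert warn and alpha0 == pytest.approx(0.25)

    def test_full_coverage_no_warning(self):
        ip, inp = np.array([1, 2, 3, 9]), np.array([1, 1, 1, 1])
        curves = allocation_curves(ip, inp)
        alpha, _ = max_separation(curves)
        warn, alpha0, _ = detect_ip_depth(ip, inp, curves, alpha)
        assert not warn and alpha0 == 0.0

    def test_all_zero_ip_rejected(self):
        ip, inp = np.zeros(4), np.ones(4)
        curves = None
        with pytest.raises(InputDataError):
            detect_ip_depth(ip, inp, curves, 0.5)


class TestAmplificationBias:
    def test_concentrated_reads_warn(self):
        cov = np.r_[30.0, np.full(199, 70 / 199)]
        warn, g = detect_amplification_bias(cov)
        assert warn and g == pytest.approx(1 / 200)

    def test_uniform_coverage_clean(self):
        warn, g = detect_amplification_bias(np.full(1000, 5.0))
        assert not warn and g == pytest.approx(0.25)

    def test_just_below_rule_boundary(self):
        # top bin has 24 of 100 reads; reaching 25% needs 2 more uniform
        # bins (76/99 reads each) -> g = 3/100 >= 1% -> clean
        cov = np.r_[24.0, np.full(99, 76 / 99)]
        warn, g = detect_amplification_bias(cov)
        assert not warn and g == pytest.approx(0.03)


class TestIpStrengthPipeline:
    def test_planted_pair_end_to_end(self, small_pair, toy_table=None):
        from chance_qc.fixtures import gen_training_table

        ip, inp = small_pair
        res = ip_strength(
            ip, inp, training=gen_training_table(n_per_cell=10, seed=3),
            n_resamples=49, seed=0,
        )
        assert res.p_value == pytest.approx(1 / 50)
        assert set(res.q_values) == set(CATEGORIES) | {"ALL"}
        assert res.pct_genome_enriched == pytest.approx(10.0, abs=3.0)

    def test_failed_alert_fires_only_when_all_qvalues_high(self):
        # craft tables around the 5% threshold: alert iff all five q-values > 0.05
        def table(ii_stats, ip_stats):
            rows = []
            for cat in CATEGORIES:
                rows += [(cat, "Input_Input", s) for s in ii_stats]
                rows += [(cat, "IP_Input", s) for s in ip_stats]
            return TrainingTable(
                pd.DataFrame(rows, columns=["category", "pair_type", "divergence_stat"])
            )

        ip, inp = np.array([1, 1, 6, 6]), np.array([2, 2, 2, 2])
        # observed d ~ 0.357; all II mass above d -> q = 10/20 = 0.5 everywhere
        high = table([0.6] * 10, [0.7] * 10)
        res = ip_strength(ip, inp, training=high, n_resamples=19, seed=0)
        assert all(v > 0.05 for v in res.q_values.values())
        assert res.failed_sample_alert
        # II mass below d -> q = 0 everywhere -> no alert
        low = table([0.1] * 10, [0.7] * 10)
        res = ip_strength(ip, inp, training=low, n_resamples=19, seed=0)
        assert not res.failed_sample_alert
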