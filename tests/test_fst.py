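"""Weir-Cockerham theta: closed forms, oracle agreement, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import nearest_rank, wc_theta_anova
from conftest import make_freq_table
from evotri.fst import (
    ThresholdSpec,
    anova_components,
    pairwise_fst_table,
    pairwise_theta,
    percentile_cutoff,
    theta_vector,
)

# value frozen from the independent ANOVA oracle (exact fraction 1766/3366)
THETA_100_02_08 = 0.5246583481877599


class TestPairwiseTheta:
    def test_fixed_difference_equal_n_is_one(self):
        assert pairwise_theta(100, 0.0, 100, 1.0) == pytest.approx(1.0, abs=1e-15)

    def test_equal_sample_frequencies_closed_form(self):
        # equal frequencies, equal n: theta = -1/(n-1)
        assert pairwise_theta(11, 0.5, 11, 0.5) == pytest.approx(-0.1, abs=1e-12)
        for n in (5, 50, 500):
            assert pairwise_theta(n, 0.3, n, 0.3) == pytest.approx(-1 / (n - 1), abs=1e-12)

    def test_pooled_monomorphic_undefined(self):
        assert math.isnan(pairwise_theta(100, 1.0, 100, 1.0))
        assert math.isnan(pairwise_theta(50, 0.0, 70, 0.0))

    def test_frozen_regression_value(self):
        assert pairwise_theta(100, 0.2, 100, 0.8) == pytest.approx(THETA_100_02_08, abs=1e-12)
        assert wc_theta_anova(100, 0.2, 100, 0.8) == pytest.approx(THETA_100_02_08, abs=1e-12)

    def test_matches_independent_anova_oracle(self, rng):
        for _ in range(1500):
            n1, n2 = rng.integers(2, 400, size=2)
            p1, p2 = rng.integers(0, n1 + 1) / n1, rng.integers(0, n2 + 1) / n2
            got = pairwise_theta(n1, p1, n2, p2)
            want = wc_theta_anova(n1, p1, n2, p2)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)
                assert got <= 1.0 + 1e-12

    @given(
        n1=st.integers(2, 300),
        n2=st.integers(2, 300),
        k1=st.integers(0, 300),
        k2=st.integers(0, 300),
    )
    @settings(max_examples=200, derandomize=True)
    def test_allele_label_invariance(self, n1, n2, k1, k2):
        # frequencies as allele-count fractions, the granularity of real data
        p1, p2 = min(k1, n1) / n1, min(k2, n2) / n2
        t = pairwise_theta(n1, p1, n2, p2)
        t_flip = pairwise_theta(n1, 1 - p1, n2, 1 - p2)
        if math.isnan(t):
            assert math.isnan(t_flip)
        else:
            assert t == pytest.approx(t_flip, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pairwise_theta(0, 0.5, 10, 0.5)
        with pytest.raises(ValueError):
            pairwise_theta(10, 1.5, 10, 0.5)
        with pytest.raises(ValueError):
            pairwise_theta(10, float("nan"), 10, 0.5)

    def test_components_consistency(self):
        c = anova_components(30, 0.25, 70, 0.6)
        assert c.r == 2
        assert c.n_bar == pytest.approx(50)
        assert c.n_c == pytest.approx(100 - (900 + 4900) / 100)
        assert c.s2 >= 0
        assert c.a / (c.a + c.b) == pytest.approx(wc_theta_anova(30, 0.25, 70, 0.6), abs=1e-12)


class TestPairwiseFstTable:
    def test_vectorized_equals_scalar(self, rng):
        rows = []
        for i in range(10):
            n1, n2 = rng.integers(10, 200, size=2)
            rows.append(
                (f"rs{i}", "chr1", 100 * (i + 1),
                 {"A": (n1, rng.random()), "B": (n2, rng.random())})
            )
        table = make_freq_table(rows, populations=("A", "B"))
        result = pairwise_fst_table(table, ("A", "B"))
        for i, row in enumerate(result.data.itertuples(index=False)):
            expect = pairwise_theta(
                table.n_chrom("A")[i], table.freq("A")[i],
                table.n_chrom("B")[i], table.freq("B")[i],
            )
            assert row.theta == pytest.approx(expect, nan_ok=True, abs=1e-14)

    def test_pair_order_symmetric(self, small_freq_table):
        t_ab = pairwise_fst_table(small_freq_table, ("A", "B"))
        t_ba = pairwise_fst_table(small_freq_table, ("B", "A"))
        np.testing.assert_allclose(t_ab.theta, t_ba.theta)

    def test_defined_count_excludes_monomorphic(self):
        rows = [("rs%d" % i, "chr1", i + 1, {"A": (50, 0.3), "B": (50, 0.6)}) for i in range(8)]
        rows += [
            ("rsM1", "chr1", 100, {"A": (50, 0.0), "B": (50, 0.0)}),
            ("rsM2", "chr1", 101, {"A": (50, 1.0), "B": (50, 1.0)}),
        ]
        result = pairwise_fst_table(make_freq_table(rows, ("A", "B")), ("A", "B"))
        assert result.defined_count == 8
        assert len(result) == 10

    def test_unknown_population_named_in_error(self, small_freq_table):
        with pytest.raises(KeyError, match="XYZ"):
            pairwise_fst_table(small_freq_table, ("A", "XYZ"))


class TestPercentileCutoff:
    def test_nearest_rank_small_examples(self):
        values = list(range(1, 21))
        assert percentile_cutoff(values, 95) == 19
        assert sum(v >= 19 for v in values) == 2
        assert percentile_cutoff(values, 5) == 1
        assert sum(v <= 1 for v in values) == 1

    def test_matches_sort_oracle_on_uniform_draws(self, rng):
        values = rng.random(1000)
        assert percentile_cutoff(values, 90) == np.sort(values)[899]
        assert percentile_cutoff(values, 90) == nearest_rank(values, 90)

    def test_nan_excluded_before_ranking(self):
        values = [math.nan, 1.0, 2.0, 3.0, math.nan]
        assert percentile_cutoff(values, 100) == 3.0
        assert percentile_cutoff(values, 1) == 1.0

    def test_empty_or_all_nan_raises(self):
        with pytest.raises(ValueError):
            percentile_cutoff([], 50)
        with pytest.raises(ValueError):
            percentile_cutoff([math.nan], 50)


class TestThresholdSpec:
    @pytest.mark.parametrize("q_high,q_low", [(95, 5), (80, 20), (100, 0), (50.5, 49.5)])
    def test_valid(self, q_high, q_low):
        ThresholdSpec(q_high, q_low)

    @pytest.mark.parametrize("q_high,q_low", [(50, 5), (95, 50), (101, 5), (95, -1)])
    def test_invalid(self, q_high, q_low):
        with pytest.raises(ValueError):
            ThresholdSpec(q_high, q_low)


class TestEstimatorBehaviorOnSimulatedData:
    """theta-hat is ~unbiased at zero drift and increases with drift."""

    def test_mean_theta_near_zero_when_latents_shared(self, rng):
        n_snps, n = 4000, 200
        p = rng.uniform(0.1, 0.9, n_snps)
        f1 = rng.binomial(n, p) / n
        f2 = rng.binomial(n, p) / n
        theta = theta_vector(np.full(n_snps, n), f1, np.full(n_snps, n), f2)
        theta = theta[np.isfinite(theta)]
        se = theta.std(ddof=1) / math.sqrt(theta.size)
        assert abs(theta.mean()) < 3 * se

    def test_mean_theta_increases_with_drift(self, rng):
        means = []
        for f in (0.01, 0.05, 0.1):
            p = rng.uniform(0.1, 0.9, 4000)
            scale = (1 - f) / f
            lat1 = rng.beta(p * scale, (1 - p) * scale)
            lat2 = rng.beta(p * scale, (1 - p) * scale)
            n = 200
            o1, o2 = rng.binomial(n, lat1) / n, rng.binomial(n, lat2) / n
            theta = theta_vector(np.full(4000, n), o1, np.full(4000, n), o2)
            means.append(np.nanmean(theta))
        assert means[0] < means[1] < means[2]
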