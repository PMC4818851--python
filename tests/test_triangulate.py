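"""Three-way ET selection, gene-window mapping, region proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_et
from conftest import make_annotation
from evotri.fst import PairwiseFstTable, ThresholdSpec
from evotri.triangulate import (
    WindowSpec,
    map_snps_to_genes,
    proportion_in_region,
    select_et_snps,
    two_way_selection,
)


def fst_table(pair, thetas, chrom="chr1"):
    ids = [f"rs{i}" for i in range(len(thetas))]
    df = pd.DataFrame(
        {"snp_id": ids, "chrom": chrom, "pos": np.arange(1, len(thetas) + 1) * 1000,
         "theta": np.asarray(thetas, float)}
    )
    return PairwiseFstTable(pair=pair, data=df, defined_count=int(np.isfinite(thetas).sum()))


def triple_tables(t_ab, t_ac, t_bc):
    return (
        fst_table(("A", "B"), t_ab),
        fst_table(("A", "C"), t_ac),
        fst_table(("B", "C"), t_bc),
    )


class TestSelectEtSnps:
    # hand-set theta triplets for ten SNPs
    T_AB = [0.9, 0.8, 0.1, 0.7, 0.05, 0.6, 0.3, 0.85, 0.2, 0.4]
    T_AC = [0.8, 0.9, 0.2, 0.6, 0.10, 0.7, 0.2, 0.05, 0.3, 0.5]
    T_BC = [0.01, 0.02, 0.5, 0.03, 0.60, 0.04, 0.3, 0.02, 0.4, 0.2]

    def test_matches_brute_force_at_80_20(self):
        sel = select_et_snps(*triple_tables(self.T_AB, self.T_AC, self.T_BC), ThresholdSpec(80, 20))
        expected = brute_force_et(
            {f"rs{i}": (self.T_AB[i], self.T_AC[i], self.T_BC[i]) for i in range(10)}, 80, 20
        )
        assert sel.snp_ids == expected
        assert expected  # fixture designed to select something

    def test_degenerate_thresholds_select_nothing_without_common_extremes(self):
        # unique values; the three extremes sit at different SNPs
        sel = select_et_snps(*triple_tables(self.T_AB, self.T_AC, self.T_BC), ThresholdSpec(100, 0))
        assert len(sel) == 0

    def test_members_satisfy_all_three_cutoffs(self):
        sel = select_et_snps(*triple_tables(self.T_AB, self.T_AC, self.T_BC), ThresholdSpec(80, 20))
        assert (sel.snps["theta_ab"] >= sel.cutoff_high_ab).all()
        assert (sel.snps["theta_ac"] >= sel.cutoff_high_ac).all()
        assert (sel.snps["theta_bc"] <= sel.cutoff_low_bc).all()

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_threshold_nesting_on_random_tables(self, seed):
        r = np.random.default_rng(seed)
        n = 60
        tables = triple_tables(r.random(n), r.random(n), r.random(n))
        sets = [
            select_et_snps(*tables, ThresholdSpec(q_high, q_low)).snp_ids
            for q_high, q_low in [(95, 5), (90, 10), (85, 15), (80, 20)]
        ]
        assert sets[0] <= sets[1] <= sets[2] <= sets[3]

    def test_similar_pair_swap_invariance(self):
        ab, ac, bc = triple_tables(self.T_AB, self.T_AC, self.T_BC)
        cb = PairwiseFstTable(pair=("C", "B"), data=bc.data, defined_count=bc.defined_count)
        sel1 = select_et_snps(ab, ac, bc, ThresholdSpec(80, 20))
        sel2 = select_et_snps(ac, ab, cb, ThresholdSpec(80, 20))
        assert sel1.snp_ids == sel2.snp_ids

    def test_undefined_theta_dropped_from_universe(self):
        t_ab = list(self.T_AB)
        t_ab[0] = np.nan
        sel = select_et_snps(*triple_tables(t_ab, self.T_AC, self.T_BC), ThresholdSpec(80, 20))
        assert sel.universe_size == 9
        assert sel.n_dropped == 1
        assert "rs0" not in sel.snp_ids

    def test_mismatched_pairs_rejected(self):
        ab, ac, bc = triple_tables(self.T_AB, self.T_AC, self.T_BC)
        with pytest.raises(ValueError):
            select_et_snps(ab, ab, bc, ThresholdSpec(95, 5))
        with pytest.raises(ValueError):
            select_et_snps(ab, ac, ab, ThresholdSpec(95, 5))


class TestMapSnpsToGenes:
    def snps(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(len(positions))], "chrom": chrom,
             "pos": positions}
        )

    def test_distance_to_gene_edge(self):
        ann = make_annotation([("G1", "chr1", 200_000, 220_000)])
        gs = map_snps_to_genes(self.snps([150_000]), ann, WindowSpec(100_000))
        assert gs.gene_ids == {"G1"}
        assert gs.support["distance"].iloc[0] == 50_000

    def test_boundary_inclusive_at_exact_window(self):
        ann = make_annotation([("G1", "chr1", 200_000, 220_000)])
        inside = map_snps_to_genes(self.snps([100_000]), ann, WindowSpec(100_000))
        outside = map_snps_to_genes(self.snps([99_999]), ann, WindowSpec(100_000))
        assert inside.gene_ids == {"G1"}
        assert outside.gene_ids == set()

    def test_snp_in_gene_body_distance_zero(self):
        ann = make_annotation([("G1", "chr1", 200_000, 220_000)])
        gs = map_snps_to_genes(self.snps([210_000]), ann, WindowSpec(0))
        assert gs.support["distance"].iloc[0] == 0

    def test_set_semantics_multiple_supporting_snps(self):
        ann = make_annotation([("G1", "chr1", 200_000, 220_000)])
        gs = map_snps_to_genes(self.snps([205_000, 210_000, 290_000]), ann, WindowSpec(100_000))
        assert len(gs) == 1
        assert gs.genes["n_support"].iloc[0] == 3

    def test_gene_count_monotone_in_window(self):
        ann = make_annotation(
            [("G1", "chr1", 100_000, 110_000), ("G2", "chr1", 400_000, 410_000),
             ("G3", "chr2", 100_000, 110_000)]
        )
        snps = self.snps([150_000])
        sizes = [len(map_snps_to_genes(snps, ann, WindowSpec(w))) for w in (0, 50_000, 300_000)]
        assert sizes == sorted(sizes)

    def test_empty_annotation_gives_empty_set(self):
        ann = make_annotation([("G1", "chr9", 1, 10)])
        gs = map_snps_to_genes(self.snps([5]), ann, WindowSpec(0))
        assert gs.gene_ids == set()


class TestProportionInRegion:
    region = ("chr1", 500_000, 600_000)

    def test_all_inside(self):
        snps = pd.DataFrame({"snp_id": ["a", "b"], "chrom": "chr1", "pos": [510_000, 590_000]})
        assert proportion_in_region(snps, self.region, WindowSpec(0)) == 1.0

    def test_wrong_chromosome_is_zero(self):
        snps = pd.DataFrame({"snp_id": ["a"], "chrom": "chr7", "pos": [550_000]})
        assert proportion_in_region(snps, self.region, WindowSpec(100_000)) == 0.0

    def test_fraction_counts_widened_boundaries(self):
        # 4 of 10 SNPs inside region +- 100 kb
        pos = [400_000, 450_000, 550_000, 700_000] + [1_000_000 + i for i in range(6)]
        snps = pd.DataFrame({"snp_id": [f"s{i}" for i in range(10)], "chrom": "chr1", "pos": pos})
        assert proportion_in_region(snps, self.region, WindowSpec(100_000)) == pytest.approx(0.4)

    def test_empty_set_undefined(self):
        empty = pd.DataFrame({"snp_id": [], "chrom": [], "pos": []})
        with pytest.raises(ValueError):
            proportion_in_region(empty, self.region)


class TestTwoWaySelection:
    def test_inclusive_nearest_rank_on_1_to_100(self):
        table = fst_table(("A", "B"), [i / 100 for i in range(1, 101)])
        sel = two_way_selection(table, 95)
        assert len(sel) == 6  # values 95..100 inclusive of the cutoff
        assert sel["theta"].min() == pytest.approx(0.95)

    def test_three_way_subset_of_two_way(self):
        t = TestSelectEtSnps
        ab, ac, bc = triple_tables(t.T_AB, t.T_AC, t.T_BC)
        sel3 = select_et_snps(ab, ac, bc, ThresholdSpec(80, 20))
        sel2 = set(two_way_selection(ab, 80)["snp_id"])
        assert sel3.snp_ids <= sel2
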