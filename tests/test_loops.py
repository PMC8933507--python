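import numpy as np
import pandas as pd
import pytest

from hicdelta.genome import BinTable, GenomeSpec, IntervalSet
from hicdelta.loops import (
    anchor_factor_enrichment,
    classify_loops,
    loop_strength,
    pair_sites,
    pileup_obs_exp,
    pileup_sum,
)
from conftest import balanced_map_from


def loop_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "ctcf_motif1", "ctcf_motif2"],
    )


class TestClassifyLoops:
    def test_exhaustive_five_loop_case(self):
        loops = loop_frame(
            [
                ("c1", 0, 10_000, "c1", 100_000, 110_000, True, True),
                ("c1", 0, 10_000, "c1", 200_000, 210_000, True, True),
                ("c1", 0, 10_000, "c1", 300_000, 310_000, True, False),
                ("c1", 500_000, 510_000, "c1", 700_000, 710_000, False, False),
                ("c1", 900_000, 910_000, "c1", 990_000, 999_000, False, False),
            ]
        )
        peaks = IntervalSet.from_records([("c1", 905_000, 906_000, "ctcf")])
        out = classify_loops(loops, [peaks])
        counts = out["loop_class"].value_counts().to_dict()
        assert counts == {"CTCF": 2, "nonCTCF": 1, "other": 2}
        # partition: exactly one class per loop
        assert out["loop_class"].notna().all() and len(out) == 5

    def test_interchromosomal_rejected(self):
        loops = loop_frame(
            [("c1", 0, 10_000, "c2", 0, 10_000, True, True),
             ("c1", 0, 10_000, "c1", 99_000, 109_000, True, True)]
        )
        with pytest.warns(RuntimeWarning, match="different chromosomes"):
            out = classify_loops(loops, [])
        assert len(out) == 1


class TestPairSites:
    def test_separation_examples(self):
        sites = IntervalSet.from_records(
            [("c1", 0, 1000), ("c1", 60_000, 61_000), ("c1", 200_000, 201_000)]
        )
        assert len(pair_sites(sites, 50_000)) == 3
        near = IntervalSet.from_records([("c1", 0, 1000), ("c1", 30_000, 31_000)])
        assert len(pair_sites(near, 50_000)) == 0

    def test_all_pairs_combinatorics(self):
        sites = IntervalSet.from_records(
            [("c1", i * 1_000_000, i * 1_000_000 + 1000) for i in range(6)]
        )
        assert len(pair_sites(sites, 50_000)) == 15


@pytest.fixture
def flat_decay_map():
    g = GenomeSpec(["c1"], [6_000_000])
    bins = BinTable(g, 10_000)
    n = len(bins)
    counts = np.full((n, n), 2.0)
    return balanced_map_from(bins, counts)


class TestPileups:
    def test_shape_and_constant_block(self, flat_decay_map):
        pairs = pd.DataFrame(
            [("c1", 1_000_000, 1_010_000, "c1", 3_000_000, 3_010_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        agg, used, dropped = pileup_sum(flat_decay_map, pairs, flank_bp=100_000)
        assert agg.shape == (21, 21) and used == 1 and dropped == 0
        np.testing.assert_allclose(agg, 2.0)

    def test_linearity_against_per_pair_extraction(self, flat_decay_map, rng):
        m = flat_decay_map
        m.counts[:] = rng.gamma(2, 1, m.counts.shape)
        m.counts[:] = (m.counts + m.counts.T) / 2
        pairs = pd.DataFrame(
            [
                ("c1", 1_000_000, 1_010_000, "c1", 3_000_000, 3_010_000),
                ("c1", 2_000_000, 2_010_000, "c1", 4_500_000, 4_510_000),
            ],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        agg, _, _ = pileup_sum(m, pairs, flank_bp=50_000)
        manual = np.zeros_like(agg)
        for _, r in pairs.iterrows():
            bi = (r["start1"] + 5_000) // 10_000
            bj = (r["start2"] + 5_000) // 10_000
            manual += m.counts[bi - 5 : bi + 6, bj - 5 : bj + 6]
        np.testing.assert_allclose(agg, manual)

    def test_edge_pairs_dropped_and_counted(self, flat_decay_map):
        pairs = pd.DataFrame(
            [("c1", 0, 10_000, "c1", 3_000_000, 3_010_000),
             ("c1", 1_000_000, 1_010_000, "c1", 3_000_000, 3_010_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        _, used, dropped = pileup_sum(flat_decay_map, pairs, flank_bp=100_000)
        assert (used, dropped) == (1, 1)

    def test_obs_exp_identical_maps_identical_pileups(self, flat_decay_map):
        pairs = pd.DataFrame(
            [("c1", 1_000_000, 1_010_000, "c1", 3_000_000, 3_010_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        a, _, _ = pileup_obs_exp(flat_decay_map, pairs)
        b, _, _ = pileup_obs_exp(flat_decay_map, pairs)
        np.testing.assert_allclose(a, b, equal_nan=True)


class TestLoopStrength:
    def test_flat_signal_zero_ratio(self, flat_decay_map):
        loops = pd.DataFrame(
            [("c1", 1_000_000, 1_010_000, "c1", 3_000_000, 3_010_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        res = loop_strength(flat_decay_map, loops)
        assert res["strength"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_planted_dot_log_ratio(self, flat_decay_map):
        m = flat_decay_map
        bi, bj = 100, 300
        m.counts[bi - 1 : bi + 2, bj - 1 : bj + 2] *= 4.0  # 30 kb dot
        loops = pd.DataFrame(
            [("c1", bi * 10_000, bi * 10_000 + 10_000,
              "c1", bj * 10_000, bj * 10_000 + 10_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        res = loop_strength(m, loops)
        # dot enrichment is diluted only by the distance-expected shift it causes
        assert res["strength"].iloc[0] == pytest.approx(np.log2(4.0), abs=0.1)

    def test_near_end_reported_missing(self, flat_decay_map):
        loops = pd.DataFrame(
            [("c1", 10_000, 20_000, "c1", 600_000, 610_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        res = loop_strength(flat_decay_map, loops)
        assert np.isnan(res["strength"].iloc[0])
        assert res["strength_note"].iloc[0] == "incomplete donut"


class TestAnchorEnrichment:
    def test_genome_wide_factor_fraction_one(self):
        g = GenomeSpec(["c1"], [1_000_000])
        loops = pd.DataFrame(
            [("c1", 100_000, 110_000, "c1", 500_000, 510_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        whole = IntervalSet.from_records([("c1", 0, 1_000_000)])
        res = anchor_factor_enrichment(loops, whole, g, n_random=20, seed=0)
        assert res["observed_fraction"] == 1.0
        assert res["enrichment_ratio"] == pytest.approx(1.0)

    def test_absent_factor_fraction_zero(self):
        g = GenomeSpec(["c1"], [1_000_000])
        loops = pd.DataFrame(
            [("c1", 100_000, 110_000, "c1", 500_000, 510_000)],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        peaks = IntervalSet.from_records([("c1", 900_000, 901_000)])
        res = anchor_factor_enrichment(loops, peaks, g, n_random=20, seed=0)
        assert res["observed_fraction"] == 0.0

    def test_random_factor_within_null_interval(self):
        g = GenomeSpec(["c1"], [10_000_000])
        rng = np.random.default_rng(3)
        loops = pd.DataFrame(
            [
                ("c1", int(a), int(a) + 10_000, "c1", int(a) + 500_000, int(a) + 510_000)
                for a in rng.integers(0, 9_000_000, 40)
            ],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        peaks = IntervalSet.from_records(
            [("c1", int(p), int(p) + 2_000) for p in rng.integers(0, 9_900_000, 200)]
        )
        res = anchor_factor_enrichment(loops, peaks, g, n_random=200, seed=1)
        lo, hi = res["null_interval_95"]
        assert lo <= res["observed_fraction"] <= hi
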