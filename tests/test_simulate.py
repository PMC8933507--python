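import numpy as np
import pytest

from hicdelta.genome import GenomeSpec
from hicdelta.simulate import (
    PerturbationConfig,
    SimulationConfig,
    apply_perturbation,
    build_expected_model,
    generate_condition_pair,
    make_tiling_tads,
    place_loops,
    planted_compartments,
    sample_contact_map,
    truth_boundaries,
)


@pytest.fixture
def toy_config(two_chrom_genome):
    return SimulationConfig(
        genome=two_chrom_genome,
        bin_size=500_000,
        depth=1_000_000,
        seed=3,
    )


class TestExpectedModel:
    def test_symmetry_positivity(self, toy_config):
        lam = build_expected_model(toy_config)
        np.testing.assert_array_equal(lam, lam.T)
        assert (lam > 0).all() and np.isfinite(lam).all()

    def test_pure_decay_without_structure(self, two_chrom_genome):
        cfg = SimulationConfig(
            genome=two_chrom_genome, bin_size=500_000,
            compartment_strength=0.0, bias_sd=0.0,
        )
        lam = build_expected_model(cfg)
        s = cfg.bins.chrom_slice("c1")
        block = lam[s, s]
        n = block.shape[0]
        for d in (1, 3, 10):
            diag = np.diagonal(block, d)
            np.testing.assert_allclose(diag, diag[0])

    def test_plaid_ratio(self, two_chrom_genome):
        delta = 0.2
        cfg = SimulationConfig(
            genome=two_chrom_genome, bin_size=500_000,
            compartment_strength=delta, bias_sd=0.0, seed=5,
        )
        lam = build_expected_model(cfg)
        comp = planted_compartments(cfg)
        s = cfg.bins.chrom_slice("c1")
        block, c = lam[s, s], comp[s]
        d = 4
        same = diff = None
        for i in range(len(c) - d):
            j = i + d
            if c[i] == c[j] and same is None:
                same = block[i, j]
            if c[i] != c[j] and diff is None:
                diff = block[i, j]
        assert same is not None and diff is not None
        assert np.isclose(same / diff, (1 + delta) / (1 - delta))

    def test_loop_dot_amplitude(self, two_chrom_genome):
        base = dict(genome=two_chrom_genome, bin_size=500_000,
                    compartment_strength=0.0, bias_sd=0.0)
        plain = build_expected_model(SimulationConfig(**base))
        loop = build_expected_model(
            SimulationConfig(**base, loop_spec=[("c1", 2_000_000, 6_000_000, 4.0, 1)])
        )
        bi, bj = 4, 12
        assert np.isclose(loop[bi, bj] / plain[bi, bj], 4.0)
        assert np.isclose(loop[bi + 3, bj + 3], plain[bi + 3, bj + 3])


class TestSampling:
    def test_seed_determinism(self, toy_config):
        lam = build_expected_model(toy_config)
        a = sample_contact_map(lam, toy_config.bins, toy_config.depth, 9)
        b = sample_contact_map(lam, toy_config.bins, toy_config.depth, 9)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = sample_contact_map(lam, toy_config.bins, toy_config.depth, 10)
        assert not np.array_equal(a.counts, c.counts)

    def test_total_count_concentration(self, toy_config):
        lam = build_expected_model(toy_config)
        depth = toy_config.depth
        m = sample_contact_map(lam, toy_config.bins, depth, 4)
        assert abs(m.total / depth - 1) < 3 * np.sqrt(1 / depth)

    def test_per_pair_mean_matches_rate(self):
        # Monte-Carlo: repeated sampling of a 50-bin toy recovers lambda
        g = GenomeSpec(["c"], [5_000_000])
        cfg = SimulationConfig(genome=g, bin_size=100_000, bias_sd=0.0,
                               compartment_strength=0.0, depth=200_000, seed=0)
        lam = build_expected_model(cfg)
        reps = 60
        acc = np.zeros_like(lam)
        for k in range(reps):
            acc += sample_contact_map(lam, cfg.bins, cfg.depth, 100 + k).counts
        scale = cfg.depth / np.triu(lam).sum()
        expected = lam * scale
        sel = expected > 5  # pairs with enough mass for a stable ratio
        ratio = (acc / reps)[sel] / expected[sel]
        assert abs(ratio.mean() - 1) < 0.02


class TestPerturbation:
    def test_identity_leaves_model_unchanged(self, toy_config):
        lam0 = build_expected_model(toy_config)
        lam1 = build_expected_model(
            apply_perturbation(toy_config, PerturbationConfig.identity())
        )
        np.testing.assert_allclose(lam0, lam1)

    def test_decay_slope_difference_on_expected_model(self, two_chrom_genome):
        cfg = SimulationConfig(genome=two_chrom_genome, bin_size=100_000,
                               compartment_strength=0.0, bias_sd=0.0)
        pert = PerturbationConfig(decay_exponent_delta=0.3,
                                  short_range_cutoff_bp=5_000_000)
        lam0 = build_expected_model(cfg)
        lam1 = build_expected_model(apply_perturbation(cfg, pert))
        s = cfg.bins.chrom_slice("c1")

        def slope(lam, dmin, dmax):
            d = np.arange(dmin, dmax)
            y = [np.diagonal(lam[s, s], k)[0] for k in d]
            return np.polyfit(np.log10(d), np.log10(y), 1)[0]

        below = slope(lam0, 2, 40) - slope(lam1, 2, 40)
        above = slope(lam0, 60, 150) - slope(lam1, 60, 150)
        assert abs(below - 0.3) < 0.02
        assert abs(above) < 0.02
        # continuity at the cutoff: perturbed never exceeds control below it
        cut = 50
        assert np.isclose(
            np.diagonal(lam1[s, s], cut)[0], np.diagonal(lam0[s, s], cut)[0]
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            PerturbationConfig(compartment_attenuation=0.0)
        with pytest.raises(ValueError):
            PerturbationConfig(class_distal_multipliers={"cLAD": -1})


class TestConditionPair:
    def test_truth_boundaries_are_block_edges(self, two_chrom_genome):
        spec = make_tiling_tads(two_chrom_genome, 500_000, 5_000_000, 2.0)
        cfg = SimulationConfig(genome=two_chrom_genome, bin_size=500_000,
                               tad_spec=spec)
        tb = truth_boundaries(cfg)
        # 25 Mb / 5 Mb blocks -> interior edges at bins 10,20,30,40 per chrom
        per_chrom = [10, 20, 30, 40]
        expect = per_chrom + [50 + e for e in per_chrom]
        assert list(tb) == expect

    def test_pair_determinism_and_truth_export(self, toy_config, tmp_path):
        pert = PerturbationConfig(compartment_attenuation=0.8)
        a = generate_condition_pair(toy_config, pert, seed=2)
        b = generate_condition_pair(toy_config, pert, seed=2)
        np.testing.assert_array_equal(a[0].counts, b[0].counts)
        np.testing.assert_array_equal(a[1].counts, b[1].counts)
        truth = a[2]
        from hicdelta.genome import read_bed, write_bed

        p = tmp_path / "comp.bed"
        ivs = truth.compartment_intervals(toy_config.bins)
        write_bed(ivs, p)
        assert read_bed(p) == ivs

    def test_loop_placement_respects_separation(self, two_chrom_genome):
        loops = place_loops(two_chrom_genome, 100_000, 5, 3.0, seed=1,
                            min_sep_bp=500_000, max_sep_bp=2_000_000)
        assert len(loops) == 10
        for chrom, a, b, k, w in loops:
            assert 500_000 <= b - a <= 2_100_000
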