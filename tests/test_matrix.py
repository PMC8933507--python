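import numpy as np
import pytest

from hicdelta.genome import BinTable, GenomeSpec, FileFormatError
from hicdelta.matrix import (
    ContactMap,
    coarsen,
    distance_zscore,
    expected_by_distance,
    ice_balance,
    observed_over_expected,
    read_matrix,
    reproducibility_correlation,
    trans_observed_expected,
    write_matrix,
)
from conftest import balanced_map_from, random_symmetric_counts


def sinkhorn_oracle(T, max_iter=20000, tol=1e-14):
    """Independent alternating-normalization balancer (diagonal excluded),
    run to machine tolerance. Returns the doubly-balanced matrix."""
    K = T.astype(float).copy()
    np.fill_diagonal(K, 0.0)
    for _ in range(max_iter):
        r = K.sum(axis=1)
        r = r / r.mean()
        if np.abs(r - 1).max() < tol:
            break
        d = np.sqrt(r)
        K = K / np.outer(d, d)
    return K


class TestTripletIO:
    def test_small_example(self, tmp_path):
        bins = BinTable(GenomeSpec(["c"], [200]), 100)
        p = tmp_path / "m.txt"
        p.write_text("0\t0\t4\n0\t1\t2\n")
        m = read_matrix(p, bins)
        np.testing.assert_array_equal(m.counts, [[4, 2], [2, 0]])

    def test_round_trip(self, tmp_path, rng):
        bins = BinTable(GenomeSpec(["c"], [900]), 100)
        counts = np.round(random_symmetric_counts(9, rng))
        m = ContactMap(bins, counts)
        p = tmp_path / "m.txt"
        write_matrix(m, p)
        np.testing.assert_array_equal(read_matrix(p, bins).counts, counts)

    def test_conflicting_mirror(self, tmp_path):
        bins = BinTable(GenomeSpec(["c"], [200]), 100)
        p = tmp_path / "m.txt"
        p.write_text("0\t1\t2\n1\t0\t3\n")
        with pytest.raises(FileFormatError, match="mirror"):
            read_matrix(p, bins)


class TestCoarsen:
    def test_sums_and_conservation(self, rng):
        bins = BinTable(GenomeSpec(["c"], [400]), 100)
        m = ContactMap(bins, np.ones((4, 4)))
        c = coarsen(m, 200)
        # merged-bin diagonal keeps unordered-pair semantics: (0,0)+(1,1)+(0,1)
        np.testing.assert_array_equal(c.counts, [[3, 4], [4, 3]])
        assert c.total == m.total

    def test_associativity(self, rng):
        bins = BinTable(GenomeSpec(["a", "b"], [800, 400]), 100)
        m = ContactMap(bins, random_symmetric_counts(12, rng))
        a = coarsen(coarsen(m, 200), 400)
        b = coarsen(m, 400)
        np.testing.assert_allclose(a.counts, b.counts)
        assert a.bins == b.bins

    def test_non_multiple_rejected(self, rng):
        bins = BinTable(GenomeSpec(["c"], [400]), 100)
        with pytest.raises(ValueError):
            coarsen(ContactMap(bins, np.zeros((4, 4))), 150)


class TestIceBalance:
    def test_already_balanced_identity(self):
        bins = BinTable(GenomeSpec(["c"], [400]), 100)
        S = sinkhorn_oracle(random_symmetric_counts(4, np.random.default_rng(0)))
        res = ice_balance(ContactMap(bins, S), mask_low_coverage_percent=0, tol=1e-10)
        np.testing.assert_allclose(res.bias, 1.0, atol=1e-6)

    def test_recovers_planted_biases(self):
        rng = np.random.default_rng(7)
        n = 6
        S = sinkhorn_oracle(random_symmetric_counts(n, rng))
        b = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 0.8])
        T = S * np.outer(b, b)
        bins = BinTable(GenomeSpec(["c"], [n * 100]), 100)
        res = ice_balance(ContactMap(bins, T), mask_low_coverage_percent=0, tol=1e-13)
        off = ~np.eye(n, dtype=bool)
        ratio = res.map.counts[off] / S[off]
        assert np.abs(ratio / ratio.mean() - 1).max() < 1e-8

    def test_zero_coverage_row_masked(self):
        bins = BinTable(GenomeSpec(["c"], [400]), 100)
        C = random_symmetric_counts(4, np.random.default_rng(1))
        C[2, :] = C[:, 2] = 0
        res = ice_balance(ContactMap(bins, C), mask_low_coverage_percent=0)
        assert res.map.mask[2]
        assert np.isnan(res.bias[2])

    def test_oracle_equivalence_random_instances(self):
        """Corrected matrix equals the alternating-normalization oracle up
        to one global factor on random matrices with planted biases."""
        rng = np.random.default_rng(42)
        n = 20
        bins = BinTable(GenomeSpec(["c"], [n * 100]), 100)
        off = ~np.eye(n, dtype=bool)
        for _ in range(10):
            S = sinkhorn_oracle(random_symmetric_counts(n, rng))
            b = np.exp(rng.normal(0, 0.5, n))
            T = S * np.outer(b, b)
            res = ice_balance(ContactMap(bins, T), mask_low_coverage_percent=0, tol=1e-13)
            ratio = res.map.counts[off] / S[off]
            assert np.abs(ratio / ratio.mean() - 1).max() < 1e-8
            assert res.final_cv < 1e-6


class TestDistanceNormalization:
    def make_map(self, n=20, rng=None):
        bins = BinTable(GenomeSpec(["c"], [n * 100]), 100)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        counts = 10.0 / np.maximum(d, 1)
        return balanced_map_from(bins, counts)

    def test_constant_diagonal_gives_unit_oe(self):
        m = self.make_map()
        oe = observed_over_expected(m)
        off = ~np.isnan(oe)
        np.testing.assert_allclose(oe[off], 1.0)

    def test_oe_profile_idempotence(self, rng):
        n = 30
        bins = BinTable(GenomeSpec(["c"], [n * 100]), 100)
        m = balanced_map_from(bins, random_symmetric_counts(n, rng))
        oe = observed_over_expected(m)
        m2 = balanced_map_from(bins, np.nan_to_num(oe))
        prof = expected_by_distance(m2).by_chrom["c"]
        valid = ~np.isnan(prof)
        np.testing.assert_allclose(prof[valid], 1.0, atol=1e-9)

    def test_zscore_normalization_identity(self, rng):
        n = 25
        bins = BinTable(GenomeSpec(["c"], [n * 100]), 100)
        m = balanced_map_from(bins, random_symmetric_counts(n, rng))
        z = distance_zscore(m)
        for d in range(1, n - 2):
            diag = np.diagonal(z, d)
            ok = ~np.isnan(diag)
            if ok.sum() >= 2:
                assert abs(diag[ok].mean()) < 1e-10
                np.testing.assert_allclose(diag[ok].std(), 1.0)

    def test_constant_map_zscores_zero(self):
        z = distance_zscore(self.make_map())
        ok = ~np.isnan(z)
        np.testing.assert_allclose(z[ok], 0.0)


class TestTransObservedExpected:
    def make_uniform(self, k=4, nb=5, level=1.0):
        names = [f"c{i}" for i in range(k)]
        bins = BinTable(GenomeSpec(names, [nb * 100] * k), 100)
        n = len(bins)
        counts = np.full((n, n), level)
        return ContactMap(bins, counts), names

    def test_uniform_gives_unit_oe(self):
        m, names = self.make_uniform()
        oe = trans_observed_expected(m)
        off = ~np.eye(len(names), dtype=bool)
        np.testing.assert_allclose(oe.to_numpy()[off], 1.0)

    def test_expected_total_matches_observed(self, rng):
        m, names = self.make_uniform()
        m.counts[:5, 5:10] *= 3.0
        m.counts[5:10, :5] *= 3.0
        oe = trans_observed_expected(m)
        # reconstruct: sum(obs) == sum(exp)  <=>  weighted mean of O/E is 1
        k = len(names)
        obs = np.zeros((k, k))
        for a in range(k):
            sa = m.bins.chrom_slice(names[a])
            for b in range(k):
                if a != b:
                    obs[a, b] = m.counts[sa, m.bins.chrom_slice(names[b])].sum()
        exp = obs / oe.to_numpy()
        assert np.isclose(np.nansum(exp), obs.sum())

    def test_scale_invariance(self, rng):
        m, _ = self.make_uniform()
        m.counts[:5, 5:10] *= 2.5
        m.counts[5:10, :5] *= 2.5
        a = trans_observed_expected(m)
        m2 = ContactMap(m.bins, m.counts * 17.0)
        b = trans_observed_expected(m2)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), equal_nan=True)

    def test_planted_preference_elevated(self):
        # many chromosomes so marginal totals absorb little of the signal
        k, nb = 20, 4
        names = [f"c{i}" for i in range(k)]
        bins = BinTable(GenomeSpec(names, [nb * 100] * k), 100)
        counts = np.ones((len(bins), len(bins)))
        s0, s1 = bins.chrom_slice("c0"), bins.chrom_slice("c1")
        counts[s0, s1] = 2.0
        counts[s1, s0] = 2.0
        oe = trans_observed_expected(ContactMap(bins, counts))
        assert oe.loc["c0", "c1"] > 1.6
        # pairs involving a preferred chromosome are depleted: its inflated
        # marginal total raises their expectation
        assert (oe.loc["c0", "c2":] < 1.0).all()
        assert (oe.loc["c1", "c2":] < 1.0).all()


class TestReproducibility:
    def test_self_score_one_and_null_near_zero(self, rng):
        n = 60
        bins = BinTable(GenomeSpec(["c"], [n * 100]), 100)
        a = balanced_map_from(bins, random_symmetric_counts(n, rng))
        b = balanced_map_from(bins, random_symmetric_counts(n, rng))
        S = reproducibility_correlation([a, a, b])
        assert S[0, 0] == 1.0
        assert np.isclose(S[0, 1], 1.0)
        assert abs(S[0, 2]) < 0.2  # independent random maps decorrelate

    def test_requires_two_maps(self, rng):
        bins = BinTable(GenomeSpec(["c"], [500]), 100)
        m = balanced_map_from(bins, random_symmetric_counts(5, rng))
        with pytest.raises(ValueError):
            reproducibility_correlation([m])
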