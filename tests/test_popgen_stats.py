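import numpy as np
import pandas as pd
import pytest

from coastgen.genotype_io import HaplotypeMatrix, PopulationMap
from coastgen.popgen_stats import (
    WindowSpec,
    ehh_profile,
    ies,
    omega,
    rsb,
    tajimas_d,
    wc_fst,
    window_grid,
    windowed_fst,
    windowed_pi,
)
from conftest import random_two_pop_fixture, variants_for
from oracles import ehh_oracle, pi_allpairs_oracle, tajimas_d_oracle, wc_fst_oracle


def _hap(rows, phased=True):
    a = np.asarray(rows, dtype=np.int8)
    return HaplotypeMatrix(a, [f"s{i}" for i in range(a.shape[0] // 2)], phased)


def _pm(hap, pop="P"):
    return PopulationMap({s: s for s in hap.sample_ids},
                         {s: pop for s in hap.sample_ids})


class TestWcFst:
    def test_complete_fixation(self, two_pop_map):
        alle = np.r_[np.zeros((20, 1)), np.ones((20, 1))].astype(np.int8)
        hap = HaplotypeMatrix(alle, [f"s{i}" for i in range(20)])
        pm = two_pop_map(10, 10)
        pm = PopulationMap({s: s for s in hap.sample_ids},
                           dict(zip(hap.sample_ids, ["A"] * 10 + ["B"] * 10)))
        res = wc_fst(hap, pm, "A", "B")
        assert res["fst"].iloc[0] == pytest.approx(1.0)

    def test_no_differentiation_near_zero(self):
        alle = np.tile([0, 1], 20).reshape(40, 1).astype(np.int8)
        hap = HaplotypeMatrix(alle, [f"s{i}" for i in range(20)])
        pm = PopulationMap({s: s for s in hap.sample_ids},
                           dict(zip(hap.sample_ids, ["A"] * 10 + ["B"] * 10)))
        res = wc_fst(hap, pm, "A", "B")
        assert abs(res["fst"].iloc[0]) < 0.1

    def test_matches_bruteforce_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            hap, pm = random_two_pop_fixture(rng, n_a=3, n_b=3, n_snps=4)
            res = wc_fst(hap, pm, "A", "B")
            for j in range(4):
                ga = [(int(hap.alleles[2 * i, j]), int(hap.alleles[2 * i + 1, j]))
                      for i in range(3)]
                gb = [(int(hap.alleles[2 * i, j]), int(hap.alleles[2 * i + 1, j]))
                      for i in range(3, 6)]
                a, b, c = wc_fst_oracle(ga, gb)
                assert res["a"].iloc[j] == pytest.approx(a, abs=1e-8)
                assert res["b"].iloc[j] == pytest.approx(b, abs=1e-8)
                assert res["c"].iloc[j] == pytest.approx(c, abs=1e-8)

    def test_windowed_equals_per_snp_for_single_snp_window(self):
        rng = np.random.default_rng(9)
        hap, pm = random_two_pop_fixture(rng, n_snps=3)
        var = variants_for(hap, spacing=100_000)
        comp = wc_fst(hap, pm, "A", "B")
        windows = window_grid({"chr1": 300_000}, WindowSpec(50_000, 50_000))
        wf = windowed_fst(comp, var, windows)
        for j in range(3):
            wi = windows.index[(windows.start <= var["pos"][j])
                               & (windows.end >= var["pos"][j])][0]
            if not np.isnan(comp["fst"].iloc[j]):
                assert wf[wi] == pytest.approx(comp["fst"].iloc[j])

    def test_windowed_fst_bounds(self):
        rng = np.random.default_rng(10)
        hap, pm = random_two_pop_fixture(rng, n_a=5, n_b=5, n_snps=50)
        var = variants_for(hap)
        windows = window_grid({"chr1": 50_000}, WindowSpec())
        wf = windowed_fst(wc_fst(hap, pm, "A", "B"), var, windows)
        ok = wf[~np.isnan(wf)]
        assert np.all(ok >= -0.1) and np.all(ok <= 1.0)


class TestWindowedPi:
    def test_single_snp_half_frequency(self):
        alle = np.array([[0], [1]], dtype=np.int8)
        hap = _hap(alle)
        var = variants_for(hap)
        windows = window_grid({"chr1": 50_000}, WindowSpec())
        pi = windowed_pi(hap, _pm(hap), "P", var, windows)
        # 2 * .5 * .5 * 2/1 = 1 pairwise difference over 50 kb
        assert pi[0] == pytest.approx(1.0 / 50_000)

    def test_monomorphic_window_zero(self):
        hap = _hap(np.zeros((10, 5), dtype=np.int8))
        var = variants_for(hap)
        windows = window_grid({"chr1": 50_000}, WindowSpec())
        pi = windowed_pi(hap, _pm(hap), "P", var, windows)
        assert pi[0] == 0.0

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(11)
        alle = rng.integers(0, 2, size=(20, 40)).astype(np.int8)
        hap = _hap(alle)
        var = variants_for(hap, spacing=1000)
        windows = window_grid({"chr1": 50_000}, WindowSpec(50_000, 50_000))
        pi = windowed_pi(hap, _pm(hap), "P", var, windows)
        expected = pi_allpairs_oracle([list(row) for row in alle]) / 50_000
        assert pi[0] == pytest.approx(expected, rel=1e-10)

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(12)
        alle = rng.integers(0, 2, size=(12, 30)).astype(np.int8)
        hap = _hap(alle)
        order = rng.permutation(6)
        rows = np.ravel([[2 * i, 2 * i + 1] for i in order])
        hap2 = HaplotypeMatrix(alle[rows], [f"s{i}" for i in order])
        var = variants_for(hap)
        windows = window_grid({"chr1": 30_000}, WindowSpec(30_000, 30_000))
        p1 = windowed_pi(hap, _pm(hap), "P", var, windows)
        p2 = windowed_pi(hap2, _pm(hap2), "P", var, windows)
        np.testing.assert_allclose(p1, p2)


class TestOmega:
    def test_equal_diversity_zero(self):
        assert omega(np.array([0.5]), np.array([0.5]))[0] == 0.0

    def test_double_diversity_one(self):
        assert omega(np.array([0.4]), np.array([0.2]))[0] == pytest.approx(1.0)

    def test_zero_diversity_missing(self):
        out = omega(np.array([0.4, 0.0]), np.array([0.0, 0.2]))
        assert np.isnan(out).all()

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError):
            omega(np.zeros(3), np.zeros(4))


class TestTajimasD:
    def test_no_segregating_sites_missing(self):
        hap = _hap(np.zeros((10, 5), dtype=np.int8))
        var = variants_for(hap)
        windows = window_grid({"chr1": 50_000}, WindowSpec())
        d = tajimas_d(hap, _pm(hap), "P", var, windows)
        assert np.isnan(d[0])

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            alle = rng.integers(0, 2, size=(10, 8)).astype(np.int8)
            if not ((alle.mean(0) > 0) & (alle.mean(0) < 1)).any():
                continue
            hap = _hap(alle)
            var = variants_for(hap, spacing=1000)
            windows = window_grid({"chr1": 8_000}, WindowSpec(8_000, 8_000))
            d = tajimas_d(hap, _pm(hap), "P", var, windows)
            expected = tajimas_d_oracle([list(r) for r in alle])
            assert d[0] == pytest.approx(expected, abs=1e-10)

    def test_singletons_only_negative(self):
        # each variant is carried by exactly one haplotype
        alle = np.zeros((10, 6), dtype=np.int8)
        for j in range(6):
            alle[j, j] = 1
        hap = _hap(alle)
        var = variants_for(hap, spacing=500)
        windows = window_grid({"chr1": 3_000}, WindowSpec(3_000, 3_000))
        d = tajimas_d(hap, _pm(hap), "P", var, windows)
        assert d[0] < 0
        assert d[0] == pytest.approx(tajimas_d_oracle([list(r) for r in alle]),
                                     abs=1e-10)


class TestEhh:
    def test_focal_value_one(self):
        rng = np.random.default_rng(14)
        alle = rng.integers(0, 2, size=(10, 9)).astype(np.int8)
        alle[:, 4] = np.tile([0, 1], 5)
        hap = _hap(alle)
        _, e = ehh_profile(hap, 4, 1)
        assert e[4] == 1.0

    def test_identical_carriers_stay_one(self):
        alle = np.tile(np.array([1, 0, 1, 1, 0, 1], dtype=np.int8), (6, 1))
        hap = _hap(alle)
        _, e = ehh_profile(hap, 2, 1)
        np.testing.assert_allclose(e, 1.0)

    def test_hand_example_four_two_split(self):
        """6 carriers splitting 4/2 at the first flanking SNP: EHH = 7/15."""
        alle = np.zeros((6, 2), dtype=np.int8)
        alle[:, 0] = 1          # all six carry the focal allele
        alle[4:, 1] = 1         # 4/2 split at the flanking SNP
        hap = _hap(alle)
        _, e = ehh_profile(hap, 0, 1)
        assert e[1] == pytest.approx(7 / 15)
        assert e[1] == pytest.approx(ehh_oracle([list(r) for r in alle], 0, 1, 1))

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(15)
        alle = rng.integers(0, 2, size=(12, 21)).astype(np.int8)
        alle[:, 10] = np.tile([0, 1], 6)
        hap = _hap(alle)
        _, e = ehh_profile(hap, 10, 1)
        assert np.all(np.diff(e[10:]) <= 1e-12)
        assert np.all(np.diff(e[:11][::-1]) <= 1e-12)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            alle = rng.integers(0, 2, size=(10, 7)).astype(np.int8)
            focal = 3
            if alle[:, focal].sum() < 2:
                continue
            hap = _hap(alle)
            _, e = ehh_profile(hap, focal, 1)
            for target in range(7):
                if target == focal:
                    continue
                assert e[target] == pytest.approx(
                    ehh_oracle([list(r) for r in alle], focal, 1, target),
                    abs=1e-12)

    def test_unphased_refused(self):
        alle = np.tile([0, 1], 6).reshape(6, 2).astype(np.int8)
        hap = _hap(alle, phased=False)
        with pytest.raises(ValueError, match="phased"):
            ehh_profile(hap, 0, 1)


class TestRsb:
    def _two_pop(self, rng, n=10, L=60):
        alle = rng.integers(0, 2, size=(4 * n, L)).astype(np.int8)
        ids = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        pm = PopulationMap(dict(zip(ids, ids)),
                           dict(zip(ids, ["A"] * n + ["B"] * n)))
        return HaplotypeMatrix(alle, ids), pm

    def test_swapping_pops_negates_ln_ratio(self):
        rng = np.random.default_rng(17)
        hap, pm = self._two_pop(rng)
        var = variants_for(hap)
        hap_a = hap.subset_samples(pm.samples_in_population("A"))
        hap_b = hap.subset_samples(pm.samples_in_population("B"))
        ies_a = ies(hap_a, var)
        ies_b = ies(hap_b, var)
        ok = (ies_a > 0) & (ies_b > 0)
        lnr_ab = np.log(ies_a[ok] / ies_b[ok])
        lnr_ba = np.log(ies_b[ok] / ies_a[ok])
        np.testing.assert_allclose(lnr_ab, -lnr_ba, atol=1e-12)

    def test_identical_populations_median_zero(self):
        rng = np.random.default_rng(18)
        hap, pm = self._two_pop(rng)
        # make B an exact copy of A
        alle = hap.alleles.copy()
        alle[20:] = alle[:20]
        hap = HaplotypeMatrix(alle, hap.sample_ids)
        var = variants_for(hap)
        z, _ = rsb(hap, pm, "A", "B", var)
        assert np.nanmedian(z) == pytest.approx(0.0, abs=1e-12)

    def test_unphased_refused(self):
        rng = np.random.default_rng(19)
        hap, pm = self._two_pop(rng)
        hap = HaplotypeMatrix(hap.alleles, hap.sample_ids, phased=False)
        with pytest.raises(ValueError):
            rsb(hap, pm, "A", "B", variants_for(hap))

    def test_planted_sweep_in_upper_tail(self, small_bundle):
        variants, hap, pop_map, _, _, _, truth = small_bundle
        windows = window_grid({"chr1": int(variants["pos"].max())}, WindowSpec())
        _, win_rsb = rsb(hap, pop_map, "north", "south", variants, windows,
                         max_extend=200)
        sweep = next(s for s in truth.sweeps if s["side"] == "A")
        m = ((windows.start <= sweep["end"])
             & (windows.end >= sweep["start"])).to_numpy()
        cutoff = np.nanpercentile(win_rsb, 90)
        assert np.nanmax(win_rsb[m]) >= cutoff
        assert np.nanmean(win_rsb[m]) > 0


class TestWindowGrid:
    def test_partial_window_rule(self):
        grid = window_grid({"chr1": 72_000}, WindowSpec(50_000, 10_000))
        # last start retained only if the stub spans >= step
        assert grid["start"].iloc[0] == 1
        assert (grid["end"] - grid["start"] + 1 >= 10_000).all()
        assert grid["end"].max() == 72_000

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(10_000, 20_000)
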