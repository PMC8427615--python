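import numpy as np
import pytest
from skbio import DistanceMatrix

from msapop import amova
from msapop.band import BandMatrix
from msapop.synthetic_data import SimParams, simulate_dataset

from conftest import random_band_matrix


def band(vals, habs, sites=None):
    vals = np.asarray(vals, dtype=float)
    n = vals.shape[0]
    sites = habs if sites is None else sites
    return BandMatrix(
        values=vals,
        sample_ids=[f"i{k}" for k in range(n)],
        habitat=list(habs),
        site=list(sites),
        locus_ids=[f"L{j}" for j in range(vals.shape[1])],
    )


class TestSquaredDistance:
    def test_identical_profiles_zero(self):
        b = band(np.ones((2, 5)), ["a", "a"])
        assert amova.squared_distance_matrix(b)[("i0", "i1")] == 0.0

    def test_mismatch_count(self):
        b = band([[0, 0, 0], [1, 1, 1]], ["a", "a"])
        assert amova.squared_distance_matrix(b)[("i0", "i1")] == 3.0

    def test_missing_data_rescaling(self):
        b = band([[1, 0, np.nan, np.nan], [0, 0, 1, np.nan]], ["a", "a"])
        assert amova.squared_distance_matrix(b)[("i0", "i1")] == pytest.approx(2.0)

    def test_disjoint_pair_errors(self):
        b = band([[1, np.nan], [np.nan, 1]], ["a", "a"])
        with pytest.raises(ValueError, match="i0.*i1"):
            amova.squared_distance_matrix(b)


class TestOneLevel:
    def test_maximal_differentiation_toy(self):
        D = np.zeros((4, 4))
        D[:2, 2:] = D[2:, :2] = 2.0
        d = DistanceMatrix(D, ids=list("abcd"))
        res = amova.amova(d, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.table.loc["total", "SS"] == pytest.approx(2.0)
        assert res.table.loc["among_groups", "SS"] == pytest.approx(2.0)
        assert res.table.loc["within_groups", "SS"] == pytest.approx(0.0)
        assert res.table.loc["among_groups", "variance"] == pytest.approx(1.0)
        assert res.phi["PhiPT"] == pytest.approx(1.0)

    def test_all_identical_degenerate(self):
        d = DistanceMatrix(np.zeros((6, 6)), ids=[f"i{k}" for k in range(6)])
        res = amova.amova(d, ["a"] * 3 + ["b"] * 3, n_perm=49, seed=0)
        assert res.phi["PhiPT"] == 0.0 and res.degenerate

    def test_single_group_rejected(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError, match="two groups"):
            amova.amova(d, ["a"] * 4, n_perm=9)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(40):
            X = (rng.random((16, 30)) < 0.5).astype(float)
            b = band(X, ["a"] * 8 + ["b"] * 8)
            d = amova.squared_distance_matrix(b)
            res = amova.amova(d, b.habitat, n_perm=99, seed=rep)
            ps.append(res.p_values["PhiPT"])
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert rate <= 0.15  # ~alpha with binomial noise at 40 replicates


class TestTwoLevel:
    def test_ss_and_df_additivity(self):
        rng = np.random.default_rng(1)
        b = random_band_matrix(rng, n=12, L=40)
        d = amova.squared_distance_matrix(b)
        res = amova.amova(d, b.habitat, b.site, n_perm=19, seed=0)
        t = res.table
        assert t.loc["total", "SS"] == pytest.approx(
            t.iloc[0]["SS"] + t.iloc[1]["SS"] + t.iloc[2]["SS"]
        )
        assert t.loc["total", "df"] == 11

    def test_matches_nested_anova_oracle_on_balanced_design(self):
        # direct nested ANOVA on the 0/1 coordinates, summed over loci
        rng = np.random.default_rng(3)
        vals = (rng.random((24, 50)) < 0.5).astype(float)
        hab = np.repeat(["A", "B", "C"], 8)
        site = np.repeat([f"s{i}" for i in range(6)], 4)
        b = band(vals, hab, site)
        res = amova.amova(amova.squared_distance_matrix(b), b.habitat, b.site, n_perm=9, seed=0)
        gm = vals.mean(0)
        hm = {h: vals[hab == h].mean(0) for h in "ABC"}
        sm = {s: vals[site == s].mean(0) for s in set(site)}
        ss_wp = sum(((vals[site == s] - sm[s]) ** 2).sum() for s in set(site))
        ss_ap = sum(4 * ((sm[s] - hm[hab[site == s][0]]) ** 2).sum() for s in set(site))
        ss_ag = sum(8 * ((hm[h] - gm) ** 2).sum() for h in "ABC")
        np.testing.assert_allclose(
            res.table["SS"].iloc[:3].to_numpy(), [ss_ag, ss_ap, ss_wp], atol=1e-10
        )
        ms_ag, ms_ap, ms_wp = ss_ag / 2, ss_ap / 3, ss_wp / 18
        sigma_oracle = [(ms_ag - ms_ap) / 8, (ms_ap - ms_wp) / 4, ms_wp]
        np.testing.assert_allclose(
            res.table["variance"].iloc[:3].to_numpy(), sigma_oracle, atol=1e-10
        )

    def test_invariance_to_locus_and_sample_order(self):
        rng = np.random.default_rng(2)
        b = random_band_matrix(rng, n=12, L=30, missing_rate=0)
        res1 = amova.amova(amova.squared_distance_matrix(b), b.habitat, b.site, n_perm=9, seed=1)
        b2 = b.select_loci(rng.permutation(30))
        perm = rng.permutation(12)
        b2 = b2.select_samples(perm)
        res2 = amova.amova(amova.squared_distance_matrix(b2), b2.habitat, b2.site, n_perm=9, seed=1)
        for k in res1.phi:
            assert res1.phi[k] == pytest.approx(res2.phi[k], abs=1e-12)

    def test_recovers_planted_theta(self):
        p = SimParams(seed=1, n_aflp=2000, n_msap=10, individuals_per_site=7,
                      n_outliers=1, outlier_theta=0.101)
        aflp, *_ = simulate_dataset(p)
        d = amova.squared_distance_matrix(aflp)
        res = amova.amova(d, aflp.habitat, aflp.site, n_perm=29, seed=0)
        assert res.phi["PhiCT"] == pytest.approx(0.10, abs=0.03)
        assert res.phi["PhiSC"] == pytest.approx(0.05, abs=0.03)


class TestPairwise:
    def test_identical_and_distinct_groups(self):
        vals = np.vstack([np.zeros((2, 6)), np.zeros((2, 6)), np.ones((2, 6))])
        b = band(vals, ["a"] * 2 + ["b"] * 2 + ["c"] * 2)
        phi, p = amova.pairwise_amova(amova.squared_distance_matrix(b), b.habitat, n_perm=19, seed=0)
        assert phi.loc["a", "b"] == pytest.approx(0.0)
        assert phi.loc["a", "c"] == pytest.approx(1.0)
        assert phi.loc["b", "c"] == pytest.approx(1.0)

    def test_group_order_invariance(self):
        rng = np.random.default_rng(4)
        b = random_band_matrix(rng, n=12, L=25, missing_rate=0)
        d = amova.squared_distance_matrix(b)
        phi1, _ = amova.pairwise_amova(d, b.habitat, n_perm=19, seed=5)
        perm = list(range(6, 12)) + list(range(6))
        b2 = b.select_samples(perm)
        phi2, _ = amova.pairwise_amova(amova.squared_distance_matrix(b2), b2.habitat, n_perm=19, seed=5)
        assert phi1.loc["H1", "H2"] == pytest.approx(phi2.loc["H2", "H1"], abs=1e-12)

    def test_planted_gradient_ordering(self):
        rng = np.random.default_rng(8)
        # three demes on a line: freq shifts 0.0 / 0.25 / 0.5
        base = rng.uniform(0.2, 0.5, 300)
        f = np.vstack([base, np.clip(base + 0.25, 0, 1), np.clip(base + 0.5, 0, 1)])
        vals = np.vstack([(rng.random((15, 300)) < f[k]).astype(float) for k in range(3)])
        b = band(vals, ["a"] * 15 + ["b"] * 15 + ["c"] * 15)
        phi, _ = amova.pairwise_amova(amova.squared_distance_matrix(b), b.habitat, n_perm=9, seed=0)
        assert phi.loc["a", "c"] > phi.loc["a", "b"]
        assert phi.loc["a", "c"] > phi.loc["b", "c"]


class TestLocusByLocus:
    def test_fixed_difference_locus(self):
        vals = np.vstack([np.zeros((8, 1)), np.ones((8, 1))])
        b = band(vals, ["a"] * 8 + ["b"] * 8)
        tab = amova.locus_by_locus_amova(b, b.habitat, n_perm=199, seed=0)
        assert tab.phi.iloc[0] == pytest.approx(1.0)
        assert tab.p.iloc[0] == pytest.approx(1 / 200, abs=0.03)

    def test_monomorphic_excluded(self):
        vals = np.hstack([np.ones((8, 1)), (np.arange(8) % 2).reshape(-1, 1)])
        b = band(vals, ["a"] * 4 + ["b"] * 4)
        tab = amova.locus_by_locus_amova(b, b.habitat, n_perm=49, seed=0)
        assert bool(tab.excluded_monomorphic.iloc[0]) is True
        assert np.isnan(tab.phi.iloc[0])
        assert bool(tab.excluded_monomorphic.iloc[1]) is False
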