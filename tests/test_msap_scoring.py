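import numpy as np
import pytest

from msapop import msap_scoring as ms
from msapop.band import BandMatrix, MsapPair
from msapop.synthetic_data import SimParams, render_replicates, simulate_dataset


def make_pair(hpa_vals, msp_vals):
    hpa_vals = np.asarray(hpa_vals, dtype=float)
    n, L = hpa_vals.shape

    def bm(v):
        return BandMatrix(
            values=np.asarray(v, dtype=float),
            sample_ids=[f"i{k}" for k in range(n)],
            habitat=["H1"] * n,
            site=["s1"] * n,
            locus_ids=[f"L{j}" for j in range(L)],
        )

    return MsapPair(bm(hpa_vals), bm(msp_vals))


class TestScoring:
    @pytest.mark.parametrize(
        "hpa,msp,state,binary",
        [
            (1, 1, ms.TYPE1_UNMETHYLATED, 0.0),
            (1, 0, ms.TYPE2_HEMIMETHYLATED, 1.0),
            (0, 1, ms.TYPE3_INTERNAL_METHYLATED, 1.0),
            (0, 0, ms.TYPE4_UNINFORMATIVE, np.nan),
            (np.nan, 1, ms.TYPE4_UNINFORMATIVE, np.nan),
        ],
    )
    def test_state_mapping(self, hpa, msp, state, binary):
        m = ms.score_methylation_states(make_pair([[hpa]], [[msp]]))
        assert m.state[0, 0] == state
        if np.isnan(binary):
            assert np.isnan(m.binary_view[0, 0])
        else:
            assert m.binary_view[0, 0] == binary
        # a (0,0) score is observed; a missing input is not
        assert m.observed[0, 0] == (np.isfinite(hpa) and np.isfinite(msp))

    def test_sample_permutation_permutes_output(self):
        rng = np.random.default_rng(0)
        h = (rng.random((8, 10)) < 0.5).astype(float)
        p = (rng.random((8, 10)) < 0.5).astype(float)
        pair = make_pair(h, p)
        m1 = ms.score_methylation_states(pair)
        perm = rng.permutation(8)
        pair2 = MsapPair(pair.hpa.select_samples(perm), pair.msp.select_samples(perm))
        m2 = ms.score_methylation_states(pair2)
        np.testing.assert_array_equal(m1.state[perm], m2.state)


class TestErrorRate:
    def test_identical_replicates_zero(self):
        rng = np.random.default_rng(1)
        v = (rng.random((4, 25)) < 0.5).astype(float)
        b = make_pair(v, v).hpa
        est = ms.estimate_error_rate([(b, b)])
        assert est.epsilon == 0.0

    def test_ratio_and_pooling(self):
        a = np.zeros((4, 25))
        b5 = a.copy()
        b5.flat[:5] = 1.0  # 5 of 100 cells differ
        b3 = a.copy()
        b3.flat[:3] = 1.0
        b7 = a.copy()
        b7.flat[5:12] = 1.0
        mk = lambda v: make_pair(v, v).hpa
        assert ms.estimate_error_rate([(mk(a), mk(b5))]).epsilon == pytest.approx(0.05)
        pooled = ms.estimate_error_rate([(mk(a), mk(b3)), (mk(a), mk(b7))])
        assert pooled.epsilon == pytest.approx(10 / 200)

    def test_no_comparable_cells_errors(self):
        v = np.full((2, 3), np.nan)
        b = BandMatrix(v, ["a", "b"], ["H"] * 2, ["s"] * 2, ["L1", "L2", "L3"])
        with pytest.raises(ValueError, match="comparable"):
            ms.estimate_error_rate([(b, b)])


class TestClassification:
    def test_all_concordant_is_nml(self):
        m = ms.score_methylation_states(make_pair(np.ones((20, 1)), np.ones((20, 1))))
        (c,) = ms.classify_loci(m, 0.05)
        assert c.label == "NML" and c.discordance == 0.0

    def test_discordance_threshold_rule(self):
        h = np.ones((20, 1))
        p = np.ones((20, 1))
        p[:6, 0] = 0  # 6 of 20 hemimethylated
        (c,) = ms.classify_loci(ms.score_methylation_states(make_pair(h, p)), 0.05)
        assert c.discordance == pytest.approx(0.30)
        assert c.label == "MSL"

    def test_discordance_equal_to_epsilon_is_nml(self):
        h = np.ones((20, 1))
        p = np.ones((20, 1))
        p[:5, 0] = 0  # discordance exactly 0.25
        (c,) = ms.classify_loci(ms.score_methylation_states(make_pair(h, p)), 0.25)
        assert c.label == "NML"

    def test_no_informative_individuals_flagged_nml(self):
        h = np.full((5, 1), np.nan)
        (c,) = ms.classify_loci(ms.score_methylation_states(make_pair(h, h)), 0.05)
        assert c.label == "NML" and c.no_informative_flag and c.n_informative == 0

    def test_observed_double_absence_counts_informative(self):
        h = np.zeros((10, 1))
        (c,) = ms.classify_loci(ms.score_methylation_states(make_pair(h, h)), 0.05)
        assert c.n_informative == 10 and c.discordance == 0.0

    def test_msl_count_nonincreasing_in_epsilon(self):
        rng = np.random.default_rng(3)
        h = (rng.random((30, 40)) < 0.8).astype(float)
        p = np.abs(h - (rng.random((30, 40)) < 0.2))
        m = ms.score_methylation_states(make_pair(h, p))
        counts = [
            sum(c.label == "MSL" for c in ms.classify_loci(m, e))
            for e in (0.0, 0.05, 0.1, 0.3, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)
        # epsilon = 0: any discordant informative individual makes a locus MSL
        for c in ms.classify_loci(m, 0.0):
            assert (c.label == "MSL") == (c.discordance > 0)


class TestBandFilters:
    def test_reasons_logged(self, toy_band_matrix):
        b = toy_band_matrix
        filtered, log = ms.apply_band_filters(b, min_carriers=1, size_range=(150, 500))
        assert log["L3"] == "size_range"  # 120 bp
        assert log["L4"] == "singleton"  # one observed carrier among three scores
        assert filtered.locus_ids == ["L1", "L2"]

    def test_min_carriers(self):
        vals = np.zeros((80, 2))
        vals[:3, 0] = 1  # 3 carriers < 4
        vals[:40, 1] = 1
        b = BandMatrix(vals, [f"i{k}" for k in range(80)], ["H"] * 80, ["s"] * 80, ["L1", "L2"])
        filtered, log = ms.apply_band_filters(b, size_range=None)
        assert log["L1"] == "min_carriers" and filtered.locus_ids == ["L2"]

    def test_singleton_nonconsensus_removed(self):
        vals = np.ones((80, 2))
        vals[0, 0] = 0  # 79 ones, 1 zero
        vals[:40, 1] = 0
        b = BandMatrix(vals, [f"i{k}" for k in range(80)], ["H"] * 80, ["s"] * 80, ["L1", "L2"])
        filtered, log = ms.apply_band_filters(b, size_range=None)
        assert log["L1"] == "singleton" and filtered.locus_ids == ["L2"]

    def test_all_removed_errors(self):
        vals = np.zeros((10, 1))
        b = BandMatrix(vals, [f"i{k}" for k in range(10)], ["H"] * 10, ["s"] * 10, ["L1"])
        with pytest.raises(ValueError, match="every locus"):
            ms.apply_band_filters(b, size_range=None)

    def test_size_filter_skipped_without_sizes(self):
        vals = np.tile([1.0, 0.0], (10, 1)).reshape(10, 2)
        vals[:, :] = np.tile(np.array([[1.0, 0.0]]), (10, 1))
        vals[5:, 1] = 1.0
        b = BandMatrix(vals, [f"i{k}" for k in range(10)], ["H"] * 10, ["s"] * 10, ["L1", "L2"])
        filtered, _ = ms.apply_band_filters(b, size_range=(150, 500))
        assert filtered.n_loci == 2  # nothing size-filtered, sizes unknown


class TestRecoveryOnSyntheticData:
    def test_msl_fraction_recovered_in_error_free_limit(self):
        params = SimParams(seed=21, n_aflp=10, n_outliers=1, n_msap=2000, error_rate=0.0)
        _, msap, _, truth = simulate_dataset(params)
        m = ms.score_methylation_states(msap)
        cls = ms.classify_loci(m, 0.0)
        frac = np.mean([c.label == "MSL" for c in cls])
        planted = len(truth.msl_locus_ids) / params.n_msap
        assert abs(frac - planted) <= 0.05

    def test_planted_msl_recovered_at_low_error(self):
        params = SimParams(seed=22, n_aflp=10, n_outliers=1, n_msap=1200, error_rate=0.02)
        _, msap, _, truth = simulate_dataset(params)
        reps = render_replicates(truth, 6, seed=5)
        eps = ms.estimate_error_rate(reps).epsilon
        cls = ms.classify_loci(ms.score_methylation_states(msap), eps)
        labels = {c.locus_id: c.label for c in cls}
        sens = np.mean([labels[l] == "MSL" for l in truth.msl_locus_ids])
        assert sens >= 0.95
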