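import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from msapop import ordination as od
from msapop.band import BandMatrix, SoilTable


class TestPcoa:
    def test_collinear_points_single_axis(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = od.pcoa(D)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_equilateral_pair_of_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = od.pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])

    def test_roundtrip_recovers_configuration(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(12, 4))
        D = squareform(pdist(Y))
        res = od.pcoa(D)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(Y - Y.mean(0), res.coordinates.to_numpy()[:, :4])
        assert disparity < 1e-8

    def test_matches_reference_implementation(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(1)
        D = squareform(pdist(rng.normal(size=(10, 3))))
        ours = od.pcoa(D)
        ref = skbio_pcoa(DistanceMatrix(D, ids=[str(i) for i in range(10)]), method="eigh")
        np.testing.assert_allclose(
            ours.eigenvalues[:5], ref.eigvals.to_numpy()[:5], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()[:, 0]),
            np.abs(ref.samples.to_numpy()[:, 0]),
            atol=1e-8,
        )

    def test_nonsymmetric_rejected(self):
        D = np.arange(9, dtype=float).reshape(3, 3)
        with pytest.raises(ValueError, match="symmetric"):
            od.pcoa(D)


class TestDistlm:
    def test_pseudo_f_matches_univariate_regression_oracle(self):
        # Euclidean G: tr(HGH) equals regression SS summed over columns
        rng = np.random.default_rng(2)
        n = 15
        x = rng.normal(size=n)
        Y = np.outer(x, [1.0, -2.0, 0.5]) + rng.normal(size=(n, 3))
        D = squareform(pdist(Y))
        (rec,) = od.distlm_marginal(D, {"x": x}, n_perm=49, seed=0)
        Yc = Y - Y.mean(0)
        X = np.column_stack([np.ones(n), x])
        H = X @ np.linalg.pinv(X)
        ss_fit = np.trace((H @ Yc).T @ (H @ Yc))
        ss_res = np.trace(((np.eye(n) - H) @ Yc).T @ ((np.eye(n) - H) @ Yc))
        f_oracle = ss_fit / (ss_res / (n - 2))
        assert rec.pseudo_f == pytest.approx(f_oracle, abs=1e-8)

    def test_first_pcoa_axis_is_best_axis_predictor(self):
        rng = np.random.default_rng(3)
        D = squareform(pdist(rng.normal(size=(14, 5))))
        axes = od.pcoa(D).coordinates
        preds = {c: axes[c].to_numpy() for c in axes.columns[:4]}
        recs = od.distlm_marginal(D, preds, n_perm=19, seed=0)
        fs = {r.predictor: r.pseudo_f for r in recs}
        assert max(fs, key=fs.get) == "PCo1"

    def test_constant_predictor_rejected(self):
        D = squareform(pdist(np.random.default_rng(4).normal(size=(8, 2))))
        with pytest.raises(ValueError, match="constant"):
            od.distlm_marginal(D, {"c": np.ones(8)}, n_perm=9)

    def test_forward_skips_duplicated_predictor(self):
        rng = np.random.default_rng(5)
        n = 20
        x = rng.normal(size=n)
        Y = np.outer(x, rng.normal(size=4)) + 0.3 * rng.normal(size=(n, 4))
        D = squareform(pdist(Y))
        path = od.distlm_forward(D, {"x1": x, "x2": x.copy()}, n_perm=199, seed=0)
        selected = [r.predictor for r in path if not r.flag]
        assert len(selected) == 1  # the duplicate is never selected

    def test_forward_orders_planted_effects(self):
        rng = np.random.default_rng(6)
        n = 30
        a, b = rng.normal(size=n), rng.normal(size=n)
        a, b = a - a.mean(), b - b.mean()
        b = b - a * (a @ b) / (a @ a)  # orthogonalize
        Y = np.outer(a, [3.0, 3.0]) + np.outer(b, [1.0, -1.0]) + 0.1 * rng.normal(size=(n, 2))
        D = squareform(pdist(Y))
        path = od.distlm_forward(D, {"weak": b, "strong": a}, n_perm=199, seed=1)
        assert [r.predictor for r in path][:2] == ["strong", "weak"]


class TestStorey:
    def test_all_ones(self):
        np.testing.assert_allclose(od.storey_qvalues(np.ones(30)), 1.0)

    def test_hand_step_up_example(self):
        # pi0 = 1 fallback at m = 4: q = BH step-up values
        q = od.storey_qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_uniform_null_matches_bh(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=1000)
        q = od.storey_qvalues(p)
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        # pi0-hat ~ 1 under the uniform null, so q ~ BH
        assert np.corrcoef(q, bh)[0, 1] > 0.99
        assert np.median(q / bh) == pytest.approx(1.0, abs=0.15)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(size=200)])
        q = od.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            od.storey_qvalues([0.0, 0.5])


class TestRda:
    def band(self, vals, sites):
        n = len(vals)
        return BandMatrix(
            values=np.asarray(vals, float),
            sample_ids=[f"i{k}" for k in range(n)],
            habitat=["H1"] * n,
            site=list(sites),
            locus_ids=[f"L{j}" for j in range(np.asarray(vals).shape[1])],
        )

    def test_tracking_variable_selected_first(self):
        rng = np.random.default_rng(9)
        n_sites, per = 6, 5
        split = np.repeat([0.0, 1.0], n_sites // 2)
        vals = np.vstack([
            (rng.random((per, 40)) < (0.15 + 0.7 * split[s])).astype(float)
            for s in range(n_sites)
        ])
        sites = np.repeat([f"s{k}" for k in range(n_sites)], per)
        soil = SoilTable(pd.DataFrame(
            {"driver": split + rng.normal(0, 0.01, n_sites), "noise": rng.normal(size=n_sites)},
            index=[f"s{k}" for k in range(n_sites)],
        ))
        res = od.rda_forward(self.band(vals, sites), soil, n_perm=199, seed=0)
        assert res.global_p < 0.05
        assert res.selected and res.selected[0].predictor == "driver"

    def test_pure_noise_low_adjusted_r2(self):
        rng = np.random.default_rng(10)
        n_sites, per = 6, 5
        vals = (rng.random((n_sites * per, 60)) < 0.5).astype(float)
        sites = np.repeat([f"s{k}" for k in range(n_sites)], per)
        soil = SoilTable(pd.DataFrame(
            {"a": rng.normal(size=n_sites), "b": rng.normal(size=n_sites)},
            index=[f"s{k}" for k in range(n_sites)],
        ))
        res = od.rda_forward(self.band(vals, sites), soil, n_perm=199, seed=1)
        assert res.adj_r2 < 0.1
        assert res.global_p > 0.01

    def test_no_variables_errors(self):
        rng = np.random.default_rng(11)
        vals = (rng.random((6, 10)) < 0.5).astype(float)
        soil = SoilTable(pd.DataFrame({"c": [1.0, 1.0]}, index=["s0", "s1"]))
        b = self.band(vals, ["s0", "s1", "s0", "s1", "s0", "s1"])
        with pytest.raises(ValueError, match="pcoa"):
            od.rda_forward(b, soil, n_perm=9)


class TestUpgma:
    def test_hand_agglomeration(self):
        d = DistanceMatrix([[0, 1, 4], [1, 0, 4], [4, 4, 0]], ids=list("ABC"))
        newick, _ = od.upgma(d)
        assert newick == "(C:2,(A:0.5,B:0.5):1.5);"

    def test_identical_individuals_join_first(self):
        d = DistanceMatrix([[0, 0, 3, 3], [0, 0, 3, 3], [3, 3, 0, 1], [3, 3, 1, 0]], ids=list("ABCD"))
        newick, _ = od.upgma(d)
        assert "(A:0,B:0)" in newick

    def test_ultrametric_recovery_with_full_support(self):
        rng = np.random.default_rng(12)
        # two clean clusters in band space
        vals = np.vstack([
            np.tile([1.0] * 15 + [0.0] * 15, (4, 1)),
            np.tile([0.0] * 15 + [1.0] * 15, (4, 1)),
        ])
        vals[::2, 0] = 1 - vals[::2, 0]  # slight within-cluster variation
        b = BandMatrix(vals, [f"i{k}" for k in range(8)], ["H1"] * 8, ["s1"] * 8,
                       [f"L{j}" for j in range(30)])
        from msapop.amova import squared_distance_matrix

        d2 = squared_distance_matrix(b)
        d = DistanceMatrix(np.sqrt(d2.data), ids=d2.ids)
        newick, supports = od.upgma(d, b, n_boot=100, seed=0)
        top = supports[frozenset(f"i{k}" for k in range(4))]
        assert top >= 95.0

    def test_topology_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, fcluster

        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 4))
        D = squareform(pdist(X))
        ids = [f"t{k}" for k in range(10)]
        newick, _ = od.upgma(DistanceMatrix(D, ids=ids))
        Z = average(pdist(X))
        two = fcluster(Z, 2, criterion="maxclust")
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        root_children = tree.seed_node.child_nodes()
        ours = {frozenset(l.taxon.label for l in c.leaf_iter()) for c in root_children}
        scipy_split = frozenset(np.array(ids)[two == 1])
        assert scipy_split in ours or frozenset(set(ids) - scipy_split) in ours
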