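"""Preprocessing contracts: QC, normalization, HVG, PCA, clustering, markers."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from rmsstates import preprocess as pp
from rmsstates.preprocess import QC_PRESETS, ClusterResult, QCThresholds


def _qc_adata(n_genes_detected, mito_frac, mouse_frac=None, n_genes_total=100):
    """One cell per entry, with the requested detected-gene count and
    mitochondrial count fraction (10 mito genes at the end)."""
    n_cells = len(n_genes_detected)
    X = np.zeros((n_cells, n_genes_total))
    for i, (ng, mf) in enumerate(zip(n_genes_detected, mito_frac)):
        n_reg = ng - (1 if mf > 0 else 0)
        X[i, :n_reg] = 1
        if mf > 0:
            # dump the whole mitochondrial mass on one MT- gene
            X[i, n_genes_total - 1] = round(mf / (1 - mf) * n_reg)
    var = pd.DataFrame(
        {"is_mitochondrial": [False] * (n_genes_total - 10) + [True] * 10},
        index=[f"G{i}" for i in range(n_genes_total - 10)]
        + [f"MT-{i}" for i in range(10)],
    )
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    if mouse_frac is not None:
        obs["mouse_read_fraction"] = mouse_frac
    return ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


class TestQCFilter:
    def test_low_gene_cell_removed_under_danielli(self):
        # <200 detected genes fails the primary-culture preset
        adata = _qc_adata([150, 250], [0.0, 0.0], n_genes_total=300)
        out = pp.qc_filter(adata, "danielli")
        assert list(out.obs_names) == ["c1"]
        assert out.uns["qc_report"]["removed_low_genes"] == 1

    def test_mouse_fraction_removed_under_wei(self):
        adata = _qc_adata([1500, 1500], [0.0, 0.0], mouse_frac=[0.07, 0.01],
                          n_genes_total=2000)
        out = pp.qc_filter(adata, "wei")
        assert list(out.obs_names) == ["c1"]
        assert out.uns["qc_report"]["removed_mouse"] == 1

    def test_permissive_thresholds_identity(self, default_cohort):
        adata, _ = default_cohort
        out = pp.qc_filter(
            adata, QCThresholds(1.0, 0, 10**9, None, "permissive")
        )
        assert list(out.obs_names) == list(adata.obs_names)

    def test_matches_brute_force_row_filter(self, default_cohort):
        adata, _ = default_cohort
        thr = QC_PRESETS["danielli"]
        out = pp.qc_filter(adata, thr)
        X = adata.X.toarray()
        mito = X[:, adata.var["is_mitochondrial"].to_numpy()].sum(axis=1)
        keep = [
            i for i in range(adata.n_obs)
            if mito[i] / X[i].sum() <= thr.max_mito_fraction
            and thr.min_genes <= (X[i] > 0).sum() <= thr.max_genes
        ]
        assert list(out.obs_names) == list(adata.obs_names[keep])

    def test_all_removed_raises(self):
        adata = _qc_adata([50, 60], [0.0, 0.0])
        with pytest.raises(pp.EmptyResultError):
            pp.qc_filter(adata, "danielli")

    def test_mito_threshold_boundary(self):
        adata = _qc_adata([1000, 1000], [0.30, 0.05], n_genes_total=2000)
        out = pp.qc_filter(adata, QCThresholds(0.15, 200, 8000))
        assert list(out.obs_names) == ["c1"]


class TestSubsample:
    def test_caps_large_samples_keeps_small(self, default_cohort):
        adata, _ = default_cohort
        out = pp.subsample_cells(adata, 100, seed=0)
        counts = out.obs["sample_id"].value_counts()
        assert (counts == 100).all()
        out2 = pp.subsample_cells(adata, 10**6, seed=0)
        assert out2.n_obs == adata.n_obs

    def test_seed_reproducible(self, default_cohort):
        adata, _ = default_cohort
        a = pp.subsample_cells(adata, 50, seed=3)
        b = pp.subsample_cells(adata, 50, seed=3)
        assert list(a.obs_names) == list(b.obs_names)


class TestLognormalize:
    def test_direct_arithmetic(self):
        X = np.zeros((1, 3))
        X[0] = [10, 9990, 0]
        adata = ad.AnnData(
            X=sp.csr_matrix(X),
            var=pd.DataFrame(index=["a", "b", "c"]),
        )
        pp.lognormalize(adata, scale_total=1e4)
        v = adata.layers["lognorm"].toarray()[0]
        assert v[0] == pytest.approx(np.log(11), abs=1e-12)
        assert v[2] == 0.0

    def test_depth_invariance(self, tiny_matrix):
        doubled = tiny_matrix.copy()
        doubled.X = tiny_matrix.X * 2
        pp.lognormalize(doubled)
        np.testing.assert_allclose(
            doubled.layers["lognorm"].toarray(),
            tiny_matrix.layers["lognorm"].toarray(),
        )

    def test_zero_total_cell_warns_and_zeros(self):
        X = np.array([[0, 0], [1, 2]])
        adata = ad.AnnData(X=sp.csr_matrix(X), var=pd.DataFrame(index=["a", "b"]))
        with pytest.warns(UserWarning, match="zero total"):
            pp.lognormalize(adata)
        assert adata.layers["lognorm"].toarray()[0].sum() == 0


class TestHVG:
    def test_constant_genes_rank_last(self, tiny_matrix):
        adata = tiny_matrix.copy()
        L = adata.layers["lognorm"].toarray()
        L[:, 0] = 1.0          # constant, positive
        adata.layers["lognorm"] = sp.csr_matrix(L)
        top = pp.select_hvg(adata, adata.n_vars - 1)
        assert adata.var_names[0] not in top

    def test_exhaustive_selection(self, tiny_matrix):
        assert set(pp.select_hvg(tiny_matrix, tiny_matrix.n_vars)) == set(
            tiny_matrix.var_names
        )
        with pytest.raises(ValueError):
            pp.select_hvg(tiny_matrix, tiny_matrix.n_vars + 1)

    def test_planted_markers_recovered_in_top_2000(self):
        from rmsstates.simulate import SimConfig, generate_cohort

        adata, truth = generate_cohort(
            SimConfig(n_samples=2, cells_per_sample=400, n_genes=3000, seed=13)
        )
        pp.lognormalize(adata)
        top = set(pp.select_hvg(adata, 2000))
        planted = [g for genes in truth.marker_assignment.values() for g in genes]
        assert np.mean([g in top for g in planted]) >= 0.9


class TestScale:
    def test_standardization_and_constant_convention(self, tiny_matrix):
        adata = tiny_matrix.copy()
        L = adata.layers["lognorm"].toarray()
        L[:, 0] = 2.5
        adata.layers["lognorm"] = sp.csr_matrix(L)
        pp.scale_genes(adata)
        Z = adata.layers["scaled"]
        assert np.allclose(Z[:, 0], 0)
        nonconst = Z[:, 1:]
        assert np.allclose(nonconst.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(nonconst.std(axis=0, ddof=1), 1, atol=1e-6)

    def test_clipping(self):
        X = np.zeros((400, 1))
        X[0, 0] = 1000       # ~20 SD outlier
        adata = ad.AnnData(X=sp.csr_matrix(X), var=pd.DataFrame(index=["a"]))
        adata.layers["lognorm"] = sp.csr_matrix(X)
        pp.scale_genes(adata, clip=10.0)
        assert adata.layers["scaled"].max() == 10.0


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(0)
        u, v = rng.normal(size=(50, 1)), rng.normal(size=(1, 30))
        X = u @ v
        adata = ad.AnnData(X=sp.csr_matrix(np.abs(X)),
                           var=pd.DataFrame(index=[f"g{i}" for i in range(30)]))
        adata.layers["lognorm"] = X
        adata.layers["scaled"] = X - X.mean(axis=0)
        pp.pca(adata, 5)
        var = adata.uns["pca_variance"]
        assert var[0] / sum(var) > 0.999

    def test_component_variances_non_increasing(self, default_cohort):
        adata, _ = default_cohort
        adata = adata.copy()
        pp.scale_genes(adata)
        scores = pp.pca(adata, 10)
        v = scores.var(axis=0)
        assert (np.diff(v) <= 1e-8).all()

    def test_reconstruction_error_monotone(self, tiny_matrix):
        adata = tiny_matrix.copy()
        pp.scale_genes(adata)
        Z = adata.layers["scaled"]
        Zc = Z - Z.mean(axis=0)
        U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
        errs = [
            np.linalg.norm(Zc - (U[:, :k] * S[:k]) @ Vt[:k]) for k in range(1, 5)
        ]
        assert (np.diff(errs) <= 1e-10).all()

    def test_gene_order_invariance(self, tiny_matrix):
        adata = tiny_matrix.copy()
        pp.scale_genes(adata)
        ref = pp.pca(adata, 3)
        perm = np.random.default_rng(1).permutation(adata.n_vars)
        shuffled = adata[:, perm].copy()
        out = pp.pca(shuffled, 3)
        np.testing.assert_allclose(out, ref, atol=1e-8)


class TestClustering:
    @staticmethod
    def _blobs(seed=0, sep=10.0, n=150):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 5))
        b = rng.normal(sep, 1, size=(n, 5))
        return np.vstack([a, b]), np.array([0] * n + [1] * n)

    @pytest.mark.parametrize("method", ["louvain", "leiden"])
    def test_two_separated_blobs_recovered(self, method):
        emb, truth = self._blobs()
        res = pp.cluster_cells(emb, resolution=0.3, seed=1, method=method)
        assert len(res.labels.cat.categories) == 2
        tab = pd.crosstab(truth, res.labels)
        assert tab.max(axis=1).sum() / len(truth) >= 0.99

    def test_cell_order_invariance_up_to_relabeling(self):
        emb, _ = self._blobs()
        res1 = pp.cluster_cells(emb, seed=1)
        perm = np.random.default_rng(2).permutation(len(emb))
        res2 = pp.cluster_cells(emb[perm], seed=1)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(
            res1.labels.to_numpy()[perm], res2.labels.to_numpy()
        ) == 1.0

    def test_tiny_resolution_single_cluster(self):
        emb, _ = self._blobs(sep=2.0)
        res = pp.cluster_cells(emb, resolution=1e-4, seed=1)
        assert len(res.labels.cat.categories) == 1

    def test_too_many_neighbors_raises(self):
        emb, _ = self._blobs(n=10)
        with pytest.raises(ValueError):
            pp.cluster_cells(emb, n_neighbors=25)


class TestFindMarkers:
    def test_planted_markers_detected(self, default_cohort):
        adata, truth = default_cohort
        labels = pd.Series(
            pd.Categorical(truth.cell_state), index=adata.obs_names, name="cluster"
        )
        clusters = ClusterResult(labels, 0.3, 20, 15, 0.0)
        table = pp.find_markers(adata, clusters)
        prog = table[table["cluster"] == "progenitor"]
        planted = set(truth.marker_assignment["progenitor"])
        found = set(prog[prog["p_adj"] < 0.01]["gene"])
        assert len(planted & found) / len(planted) >= 0.9

    def test_pct_filter_excludes_rare_genes(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(60, 30)).astype(float)
        X[:30, 0] = 0
        X[30:, 0] = 0
        X[30:33, 0] = 50       # huge lfc but only 10% of the cluster
        adata = ad.AnnData(X=sp.csr_matrix(X),
                           var=pd.DataFrame(index=[f"g{i}" for i in range(30)]))
        pp.lognormalize(adata)
        labels = pd.Series(
            pd.Categorical(["a"] * 30 + ["b"] * 30),
            index=adata.obs_names, name="cluster",
        )
        table = pp.find_markers(
            adata, ClusterResult(labels, 0.3, 20, 15, 0.0), min_pct=0.25
        )
        assert "g0" not in set(table[table["cluster"] == "b"]["gene"])

    def test_exact_pvalues_match_scipy_exact(self):
        """Small, tie-free groups take the exact rank-sum path; it must agree
        with an independent exact implementation."""
        rng = np.random.default_rng(5)
        xin = rng.normal(3, 1, size=(8, 6))
        xout = rng.normal(0, 1, size=(9, 6))
        X = np.expm1(np.vstack([xin, xout]).clip(0))  # positive, tie-free
        adata = ad.AnnData(X=sp.csr_matrix(X),
                           var=pd.DataFrame(index=[f"g{i}" for i in range(6)]))
        adata.layers["lognorm"] = np.log1p(X)
        labels = pd.Series(
            pd.Categorical(["a"] * 8 + ["b"] * 9),
            index=adata.obs_names, name="cluster",
        )
        table = pp.find_markers(
            adata, ClusterResult(labels, 0.3, 20, 15, 0.0),
            lfc_min=-10, min_pct=0.0,
        )
        sub = table[table["cluster"] == "a"].set_index("gene")
        L = adata.layers["lognorm"]
        for g in sub.index:
            gi = list(adata.var_names).index(g)
            expected = stats.mannwhitneyu(
                L[:8, gi], L[8:, gi], alternative="two-sided", method="exact"
            ).pvalue
            assert sub.loc[g, "p"] == pytest.approx(expected, rel=1e-9)

    def test_null_genes_rarely_reported(self):
        """Genes identically distributed across clusters pass the lfc=0.25
        filter in well under 5% of cases."""
        rng = np.random.default_rng(7)
        reported = total = 0
        for _ in range(30):
            X = rng.poisson(1.5, size=(200, 50)).astype(float)
            adata = ad.AnnData(
                X=sp.csr_matrix(X),
                var=pd.DataFrame(index=[f"g{i}" for i in range(50)]),
            )
            pp.lognormalize(adata)
            labels = pd.Series(
                pd.Categorical(rng.permutation(["a"] * 100 + ["b"] * 100)),
                index=adata.obs_names, name="cluster",
            )
            table = pp.find_markers(adata, ClusterResult(labels, 0.3, 20, 15, 0.0))
            reported += len(table)
            total += 2 * 50
        assert reported / total < 0.05

    def test_tiny_cluster_skipped_with_warning(self, tiny_matrix):
        labels = pd.Series(
            pd.Categorical(["a", "a", "a", "b", "b"]),
            index=tiny_matrix.obs_names, name="cluster",
        )
        with pytest.warns(UserWarning, match="skipped"):
            pp.find_markers(tiny_matrix, ClusterResult(labels, 0.3, 20, 15, 0.0))
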