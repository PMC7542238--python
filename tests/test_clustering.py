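import numpy as np
import pytest
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from oracles import cophenetic_pairs_bruteforce, medoid_bruteforce
from snproi.clustering import (DistanceMatrix, LDMatrix, SNPGroups, build_groups,
                               cophenetic_correlation, filter_redundant,
                               hierarchical_cluster, ld_r2, linkage_distance_screen,
                               snp_distance, LDHierarchicalFilter)
from snproi.io import GenotypeMatrix


def _geno(values):
    values = np.asarray(values)
    return GenotypeMatrix(values, [f"snp{j}" for j in range(values.shape[1])],
                          [f"s{i}" for i in range(values.shape[0])])


class TestSnpDistance:
    def test_minkowski_r2_equals_euclidean(self, rng):
        X = rng.integers(0, 3, size=(30, 8))
        d2 = snp_distance(X, "minkowski", r=2.0).values
        de = snp_distance(X, "euclidean").values
        np.testing.assert_allclose(d2, de, atol=1e-12)

    def test_minkowski_r1_equals_absolute(self, rng):
        X = rng.integers(0, 3, size=(30, 8))
        d1 = snp_distance(X, "minkowski", r=1.0).values
        da = snp_distance(X, "absolute").values
        np.testing.assert_allclose(d1, da, atol=1e-12)

    def test_hand_minkowski_r1(self):
        X = np.array([[0, 1], [0, 2]])  # columns u=(0,0), v=(1,2)
        d = snp_distance(X, "minkowski", r=1.0).values
        assert d[0, 1] == pytest.approx(3.0)

    def test_identical_columns_zero(self):
        X = np.array([[1, 1], [2, 2], [0, 0]])
        assert snp_distance(X, "euclidean").values[0, 1] == 0.0

    def test_fractional_r_warns_and_matches_definition(self):
        X = np.array([[0, 1], [0, 2], [1, 0]], dtype=float)
        r = 0.5
        with pytest.warns(UserWarning, match="not a metric"):
            d = snp_distance(X, "minkowski", r=r).values
        expected = (abs(0 - 1) ** r + abs(0 - 2) ** r + abs(1 - 0) ** r) ** (1 / r)
        assert d[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError, match="r must be > 0"):
            snp_distance(np.zeros((3, 2)), "minkowski", r=-1.0)

    def test_variance_weighted_definition(self, rng):
        X = rng.integers(0, 3, size=(10, 5)).astype(float)
        d = snp_distance(X, "variance_weighted").values
        s2 = X.var(axis=1)
        manual = np.sqrt(np.sum((X[:, 0] - X[:, 1]) ** 2 / s2))
        assert d[0, 1] == pytest.approx(manual, rel=1e-12)

    def test_variance_weighted_constant_sample_error(self):
        X = np.array([[1, 1, 1], [0, 1, 2]])
        with pytest.raises(ValueError, match="sample index 0"):
            snp_distance(X, "variance_weighted")

    @pytest.mark.parametrize("kind", ["euclidean", "absolute", "minkowski",
                                      "variance_weighted"])
    def test_output_invariants(self, rng, kind):
        X = rng.integers(0, 3, size=(25, 7)).astype(float)
        X += 1e-9 * rng.standard_normal(X.shape)  # avoid constant samples
        d = snp_distance(X, kind, r=1.7).values
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()


class TestLdR2:
    def test_identical_and_anticorrelated_columns(self):
        X = np.array([[0, 2], [1, 1], [2, 0], [0, 2]])
        r2 = ld_r2(X).values
        assert r2[0, 1] == pytest.approx(1.0)

    def test_hand_zero_correlation(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert ld_r2(X).values[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_matches_pearson_squared(self, rng):
        X = rng.integers(0, 3, size=(40, 5)).astype(float)
        r2 = ld_r2(X).values
        for a in range(5):
            for b in range(a + 1, 5):
                expect = pearsonr(X[:, a], X[:, b]).statistic ** 2
                assert r2[a, b] == pytest.approx(expect, abs=1e-10)

    def test_constant_column_flagged_zero(self):
        X = np.array([[1, 0], [1, 1], [1, 2]])
        ld = ld_r2(X)
        assert ld.constant_snps[0] and not ld.constant_snps[1]
        assert ld.values[0, 1] == 0.0 and ld.values[0, 0] == 0.0
        assert ld.values[1, 1] == 1.0


class TestHierarchicalCluster:
    points = np.array([[0.0], [1.0], [10.0]]).T  # 1 sample, 3 "SNPs" at 0,1,10

    def _dist(self):
        X = np.array([[0.0, 1.0, 10.0]])
        vals = np.abs(X.T - X)
        return DistanceMatrix(vals, "euclidean")

    def test_single_linkage_hand_merges(self):
        t = hierarchical_cluster(self._dist(), "single")
        np.testing.assert_allclose(t.merges[:, 2], [1.0, 9.0])
        assert set(t.merges[0, :2].astype(int)) == {0, 1}

    def test_complete_linkage_hand_merges(self):
        t = hierarchical_cluster(self._dist(), "complete")
        np.testing.assert_allclose(t.merges[:, 2], [1.0, 10.0])

    def test_two_leaves_single_merge(self):
        d = DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), "euclidean")
        t = hierarchical_cluster(d, "average")
        assert t.merges.shape == (1, 4)
        assert t.merges[0, 2] == pytest.approx(3.0)

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(DistanceMatrix(np.zeros((1, 1)), "euclidean"), "single")

    def test_monotone_heights_non_centroid(self, rng):
        X = rng.integers(0, 3, size=(30, 10))
        d = snp_distance(X, "euclidean")
        for link in ("single", "complete", "average", "ward"):
            t = hierarchical_cluster(d, link)
            assert np.all(np.diff(t.merges[:, 2]) >= -1e-12)

    def test_newick_export(self):
        t = hierarchical_cluster(self._dist(), "single")
        nwk = t.to_newick(["a", "b", "c"])
        assert nwk.endswith(";") and nwk.count(",") == 2
        for name in ("a", "b", "c"):
            assert name in nwk


class TestCopheneticCorrelation:
    def test_ultrametric_gives_one(self):
        vals = squareform([1.0, 2.0, 2.0])
        d = DistanceMatrix(vals, "euclidean")
        t = hierarchical_cluster(d, "single")
        assert cophenetic_correlation(t, d) == pytest.approx(1.0)

    def test_relabeling_invariance(self, rng):
        X = rng.integers(0, 3, size=(40, 6)).astype(float)
        d = snp_distance(X, "euclidean")
        perm = rng.permutation(6)
        dp = DistanceMatrix(d.values[np.ix_(perm, perm)], "euclidean")
        c1 = cophenetic_correlation(hierarchical_cluster(d, "average"), d)
        c2 = cophenetic_correlation(hierarchical_cluster(dp, "average"), dp)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_matches_bruteforce_pair_enumeration(self, rng):
        X = rng.integers(0, 3, size=(50, 6)).astype(float)
        d = snp_distance(X, "euclidean")
        t = hierarchical_cluster(d, "average")
        coph = cophenetic_pairs_bruteforce(t.merges, 6)
        expect = pearsonr(d.condensed(), coph).statistic
        assert cophenetic_correlation(t, d) == pytest.approx(expect, abs=1e-12)

    def test_single_linkage_subdominant(self, rng):
        X = rng.integers(0, 3, size=(30, 8)).astype(float)
        d = snp_distance(X, "euclidean")
        t = hierarchical_cluster(d, "single")
        coph = cophenetic_pairs_bruteforce(t.merges, 8)
        assert np.all(coph <= d.condensed() + 1e-12)

    def test_pair_only_rejected(self):
        d = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), "euclidean")
        t = hierarchical_cluster(d, "single")
        with pytest.raises(ValueError, match="p < 3"):
            cophenetic_correlation(t, d)


class TestFilterRedundant:
    def test_identity_when_all_clusters(self, small_dataset):
        g = small_dataset.genotypes
        d = snp_distance(g, "euclidean")
        t = hierarchical_cluster(d, "average")
        out = filter_redundant(g, t, d, n_clusters=g.p_snps)
        assert out.snp_ids == g.snp_ids

    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(40, 4))
        X[:, 1] = X[:, 0]  # duplicate pair
        g = _geno(X)
        d = snp_distance(g, "euclidean")
        t = hierarchical_cluster(d, "single")
        out = filter_redundant(g, t, d, n_clusters=3)
        kept = set(out.snp_ids)
        assert len(kept & {"snp0", "snp1"}) == 1
        assert {"snp2", "snp3"} <= kept

    def test_matches_bruteforce_medoids(self, rng):
        X = rng.integers(0, 3, size=(40, 5))
        g = _geno(X)
        d = snp_distance(g, "euclidean")
        t = hierarchical_cluster(d, "average")
        labels = t.cut(2)
        expected = sorted(
            medoid_bruteforce(np.flatnonzero(labels == lab), d.values)
            for lab in np.unique(labels))
        out = filter_redundant(g, t, d, n_clusters=2)
        assert [g.snp_ids.index(s) for s in out.snp_ids] == expected

    def test_out_of_range_rejected(self, small_dataset):
        g = small_dataset.genotypes
        d = snp_distance(g, "euclidean")
        t = hierarchical_cluster(d, "average")
        with pytest.raises(ValueError, match="out of range"):
            filter_redundant(g, t, d, n_clusters=0)


class TestBuildGroups:
    def test_unreachable_threshold_gives_singletons(self, rng):
        X = rng.integers(0, 3, size=(30, 6))
        groups = build_groups(X, mode="ld", threshold=1.01)
        assert groups.n_groups == 6
        assert (groups.sizes == 1).all()

    def test_chained_components(self):
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        r2[1, 2] = r2[2, 1] = 0.3
        r2[0, 2] = r2[2, 0] = 0.01
        groups = build_groups(np.zeros((2, 3)), mode="ld", ld=LDMatrix(r2),
                              threshold=0.2)
        assert groups.n_groups == 1  # transitively chained through SNP 1

    def test_gene_grouping(self):
        g = _geno(np.zeros((2, 3), dtype=int))
        groups = build_groups(g, mode="gene",
                              gene_of={"snp0": "G1", "snp1": "G1", "snp2": "G2"})
        assert groups.assignment[0] == groups.assignment[1] != groups.assignment[2]

    def test_unannotated_snps_become_singletons(self):
        g = _geno(np.zeros((2, 3), dtype=int))
        groups = build_groups(g, mode="gene", gene_of={"snp0": "G1", "snp1": "G1"})
        assert groups.n_groups == 2

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="gene"):
            build_groups(np.zeros((2, 3)), mode="gene")
        with pytest.raises(ValueError, match="unknown grouping"):
            build_groups(np.zeros((2, 3)), mode="chromosome")

    def test_order_invariance_up_to_relabeling(self, small_dataset, rng):
        X = small_dataset.genotypes.values
        g1 = build_groups(X, mode="ld", threshold=0.2)
        perm = rng.permutation(X.shape[1])
        g2 = build_groups(X[:, perm], mode="ld", threshold=0.2)
        # same partition: co-membership matrices agree after undoing the permutation
        co1 = g1.assignment[:, None] == g1.assignment[None, :]
        a2 = np.empty_like(g2.assignment)
        a2[perm] = g2.assignment
        co2 = a2[:, None] == a2[None, :]
        np.testing.assert_array_equal(co1, co2)


class TestLinkageDistanceScreen:
    def test_grid_shape_and_range(self, rng):
        # iid uniform codes: every sample varies across SNPs, so the
        # variance-weighted distance is defined
        g = _geno(rng.integers(0, 3, size=(40, 12)))
        grid = linkage_distance_screen(g)
        assert grid.shape == (4, 5)
        vals = grid.to_numpy(dtype=float)
        assert np.all((vals >= -1) & (vals <= 1))
        kind, link, best = grid.attrs["best"]
        assert vals.max() == pytest.approx(best)

    def test_ultrametric_data_scores_one(self):
        # two duplicated columns and one distinct column: distances (0, a, a)
        # are ultrametric, so every linkage reproduces them exactly
        X = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1], [0, 0, 2]])
        grid = linkage_distance_screen(_geno(X))
        assert grid.loc["euclidean", "single"] == pytest.approx(1.0)
        assert grid.attrs["best"][2] == pytest.approx(1.0)

    def test_cells_match_composed_calls(self, rng):
        g = _geno(rng.integers(0, 3, size=(40, 10)))
        grid = linkage_distance_screen(g, minkowski_r=0.23)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for kind, link in (("euclidean", "ward"), ("minkowski", "single"),
                               ("variance_weighted", "complete")):
                d = snp_distance(g, kind, r=0.23)
                expect = cophenetic_correlation(hierarchical_cluster(d, link), d)
                assert grid.loc[kind, link] == pytest.approx(expect, abs=1e-12)


class TestLDHierarchicalFilterEstimator:
    def test_fit_transform_and_support(self, small_dataset):
        X = small_dataset.genotypes.values.astype(float)
        f = LDHierarchicalFilter(n_clusters=20).fit(X)
        Xt = f.transform(X)
        assert Xt.shape == (X.shape[0], len(f.support_))
        assert len(f.support_) <= 20
        assert np.all(np.diff(f.support_) > 0)
        np.testing.assert_array_equal(Xt, X[:, f.support_])

    def test_default_halves_panel(self, small_dataset):
        X = small_dataset.genotypes.values.astype(float)
        f = LDHierarchicalFilter().fit(X)
        assert len(f.support_) <= X.shape[1] // 2

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        f = LDHierarchicalFilter(distance="absolute", n_clusters=5)
        f2 = clone(f)
        assert f2.get_params() == f.get_params()
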