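import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from menkit.diversity import (
    DistanceMatrix,
    alpha_diversity,
    bray_curtis_matrix,
    compare_groups,
    dissimilarity_test,
    pcoa,
)
from menkit.errors import AnalysisError

from .conftest import make_table


def dist_from_points(points):
    d = squareform(pdist(points))
    return DistanceMatrix(d, [f"S{i}" for i in range(len(points))])


class TestAlphaDiversity:
    def test_no_singletons_chao1_is_sobs(self):
        table = make_table([[2], [3], [2]])
        out = alpha_diversity(table)
        assert out.loc["S0", "chao1"] == 3

    def test_uniform_four_species(self):
        table = make_table([[5], [5], [5], [5]])
        out = alpha_diversity(table)
        assert out.loc["S0", "shannon"] == pytest.approx(np.log(4))
        assert out.loc["S0", "dominance"] == pytest.approx(0.25)

    def test_chao1_formula(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        counts = np.array([[1], [1], [1], [1], [2], [2], [3], [4], [5], [6]])
        out = alpha_diversity(make_table(counts))
        assert out.loc["S0", "chao1"] == pytest.approx(12.0)

    def test_all_zero_sample_is_missing(self):
        out = alpha_diversity(make_table([[0, 1], [0, 2]]))
        assert out.loc["S0"].isna().all()
        assert out.loc["S1"].notna().all()


class TestBrayCurtis:
    def test_identical_samples(self):
        d = bray_curtis_matrix(make_table([[3, 3], [1, 1]]))
        assert d.data[0, 1] == 0

    def test_disjoint_supports(self):
        d = bray_curtis_matrix(make_table([[3, 0], [0, 5]]))
        assert d.data[0, 1] == 1

    def test_hand_value(self):
        d = bray_curtis_matrix(make_table([[1, 0], [1, 1], [0, 1]]))
        assert d.data[0, 1] == pytest.approx(0.5)

    def test_two_zero_samples_error(self):
        with pytest.raises(AnalysisError, match="all-zero"):
            bray_curtis_matrix(make_table([[0, 0, 1], [0, 0, 2]]))

    def test_symmetry_and_range(self, rng):
        d = bray_curtis_matrix(make_table(rng.integers(0, 20, (10, 6))))
        assert np.allclose(d.data, d.data.T)
        assert (d.data >= 0).all() and (d.data <= 1).all()
        assert np.allclose(np.diag(d.data), 0)


class TestPcoa:
    def test_euclidean_embedding_exact(self, rng):
        points = rng.normal(size=(8, 2))
        ord_ = pcoa(dist_from_points(points), k=2)
        rebuilt = squareform(pdist(ord_.coordinates))
        np.testing.assert_allclose(rebuilt, squareform(pdist(points)), atol=1e-8)

    def test_duplicate_samples_identical_coords(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
        ord_ = pcoa(dist_from_points(pts), k=1)
        assert ord_.coordinates[0, 0] == pytest.approx(ord_.coordinates[1, 0])

    def test_matches_dense_eigensolver(self, rng):
        pts = rng.normal(size=(4, 3))
        dist = dist_from_points(pts)
        # brute-force oracle: explicit double-centered eigendecomposition
        d2 = dist.data**2
        n = 4
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        lam = np.sort(np.linalg.eigvalsh(b))[::-1]
        ord_ = pcoa(dist, k=3)
        np.testing.assert_allclose(ord_.eigenvalues, lam[lam > 1e-10], atol=1e-9)

    def test_too_many_axes_warns(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            ord_ = pcoa(dist_from_points(pts), k=3)
        assert ord_.coordinates.shape[1] == 1

    def test_variance_explained_sums_to_one(self, rng):
        pts = rng.normal(size=(6, 4))
        ord_ = pcoa(dist_from_points(pts), k=2)
        assert ord_.proportion_explained.sum() == pytest.approx(1.0)


class TestDissimilarityTests:
    @pytest.fixture
    def separated(self, rng):
        a = rng.normal(0, 0.05, size=(6, 3))
        b = rng.normal(10, 0.05, size=(6, 3))
        return dist_from_points(np.vstack([a, b])), ["A"] * 6 + ["B"] * 6

    def test_perfect_separation_anosim(self, separated):
        dist, labels = separated
        res = dissimilarity_test(dist, labels, "anosim", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_perfect_separation_adonis_mrpp(self, separated):
        dist, labels = separated
        for method in ("adonis", "mrpp"):
            res = dissimilarity_test(dist, labels, method, n_perm=99, seed=0)
            assert res.p_value == pytest.approx(1 / 100)

    def test_random_split_mrpp_a_near_zero(self, rng):
        pts = rng.normal(size=(20, 4))
        labels = ["A"] * 10 + ["B"] * 10
        res = dissimilarity_test(dist_from_points(pts), labels, "mrpp", n_perm=199, seed=1)
        assert abs(res.extra["A"]) < 0.1

    def test_label_renaming_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        dist = dist_from_points(pts)
        l1 = ["A"] * 6 + ["B"] * 6
        l2 = ["B"] * 6 + ["A"] * 6
        for method in ("anosim", "adonis", "mrpp"):
            r1 = dissimilarity_test(dist, l1, method, n_perm=99, seed=3)
            r2 = dissimilarity_test(dist, l2, method, n_perm=99, seed=3)
            assert r1.statistic == pytest.approx(r2.statistic)
            assert r1.p_value == pytest.approx(r2.p_value)

    def test_anosim_r_bounds(self, rng):
        pts = rng.normal(size=(14, 3))
        res = dissimilarity_test(
            dist_from_points(pts), ["A"] * 7 + ["B"] * 7, "anosim", n_perm=49, seed=2
        )
        assert -1 <= res.statistic <= 1

    def test_singleton_group_errors(self, rng):
        pts = rng.normal(size=(5, 2))
        with pytest.raises(AnalysisError):
            dissimilarity_test(dist_from_points(pts), ["A"] * 4 + ["B"], "anosim")

    def test_seed_reproducibility(self, rng):
        pts = rng.normal(size=(12, 3))
        dist = dist_from_points(pts)
        labels = ["A"] * 6 + ["B"] * 6
        a = dissimilarity_test(dist, labels, "adonis", n_perm=99, seed=5)
        b = dissimilarity_test(dist, labels, "adonis", n_perm=99, seed=5)
        assert a.p_value == b.p_value


class TestCompareGroups:
    def test_normal_data_takes_t_branch(self):
        chosen = 0
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            res = compare_groups(r.normal(size=20), r.normal(size=20))
            if res.extra["branch"] in ("t-test", "welch-t"):
                chosen += 1
        assert chosen >= 40

    def test_exponential_data_takes_wilcoxon(self):
        chosen = 0
        for rep in range(50):
            r = np.random.default_rng(2000 + rep)
            res = compare_groups(r.exponential(size=30), r.exponential(size=30))
            if res.extra["branch"] == "wilcoxon":
                chosen += 1
        assert chosen >= 45

    def test_constant_input_falls_back(self):
        res = compare_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.extra["branch"] == "wilcoxon"

    def test_too_few_values(self):
        with pytest.raises(AnalysisError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
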