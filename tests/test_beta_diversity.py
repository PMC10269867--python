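import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.diversity.beta import (
    unweighted_unifrac as skbio_uu,
    weighted_unifrac as skbio_wu,
)
from skbio.stats.distance import permanova as skbio_permanova

from aviphylosym import beta_diversity as bd
from conftest import random_table
from oracles import (
    permanova_ss_oracle,
    unweighted_unifrac_oracle,
    weighted_unifrac_oracle,
)


def _random_instances(random_tree_factory, rng, n_instances=20, n_tips=8):
    tree = random_tree_factory(n_tips, seed=17, prefix="asv")
    asv_ids = sorted(t.name for t in tree.tips())
    for _ in range(n_instances):
        a = rng.integers(0, 30, size=n_tips)
        b = rng.integers(0, 30, size=n_tips)
        a[rng.integers(n_tips)] += 1
        b[rng.integers(n_tips)] += 1
        yield tree, asv_ids, a, b


class TestUnweightedUnifrac:
    def test_identical_presence_sets_give_zero(self, star_tree):
        ids = [f"t{i}" for i in range(8)]
        assert bd.unweighted_unifrac([1] * 8, [2] * 8, ids, star_tree) == 0.0

    def test_disjoint_sets_on_star_tree_give_one(self, star_tree):
        ids = [f"t{i}" for i in range(8)]
        a = [1, 1, 1, 1, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1]
        assert bd.unweighted_unifrac(a, b, ids, star_tree) == 1.0

    def test_matches_edge_set_oracle_and_skbio(self, random_tree_factory, rng):
        for tree, ids, a, b in _random_instances(random_tree_factory, rng):
            ours = bd.unweighted_unifrac(a, b, ids, tree)
            present_a = [i for i, c in zip(ids, a) if c > 0]
            present_b = [i for i, c in zip(ids, b) if c > 0]
            oracle = unweighted_unifrac_oracle(tree, present_a, present_b)
            assert ours == pytest.approx(oracle, abs=1e-10)
            assert ours == pytest.approx(
                float(skbio_uu(a, b, taxa=ids, tree=tree)), abs=1e-10
            )

    def test_empty_sample_is_error(self, star_tree):
        ids = [f"t{i}" for i in range(8)]
        with pytest.raises(ValueError):
            bd.unweighted_unifrac([0] * 8, [1] * 8, ids, star_tree)


class TestWeightedUnifrac:
    def test_identical_relative_abundances_give_zero(self, star_tree):
        ids = [f"t{i}" for i in range(8)]
        a = np.arange(1, 9)
        assert bd.weighted_unifrac(a, 3 * a, ids, star_tree) == pytest.approx(0.0)

    def test_disjoint_halves_of_star_tree_normalized_one(self, star_tree):
        ids = [f"t{i}" for i in range(8)]
        a = [1, 1, 1, 1, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1]
        assert bd.weighted_unifrac(a, b, ids, star_tree) == pytest.approx(1.0)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_per_branch_oracle_and_skbio(
        self, random_tree_factory, rng, normalized
    ):
        for tree, ids, a, b in _random_instances(random_tree_factory, rng):
            ours = bd.weighted_unifrac(a, b, ids, tree, normalized=normalized)
            oracle = weighted_unifrac_oracle(
                tree, dict(zip(ids, a)), dict(zip(ids, b)), normalized=normalized
            )
            assert ours == pytest.approx(oracle, abs=1e-10)
            assert ours == pytest.approx(
                float(skbio_wu(a, b, taxa=ids, tree=tree, normalized=normalized)),
                abs=1e-10,
            )


class TestDistanceMatrix:
    def test_single_sample(self, star_tree, rng):
        table = random_table(rng, n_samples=1, n_asvs=8, prefix="t").rename(
            columns=lambda c: c.replace("t000", "t").replace("t00", "t")
        )
        table.columns = [f"t{i}" for i in range(8)]
        dm = bd.distance_matrix(table, star_tree)
        assert dm.shape == (1, 1)
        assert dm.data[0, 0] == 0.0

    @pytest.mark.parametrize("metric", ["weighted_unifrac", "unweighted_unifrac"])
    def test_matches_elementwise_pairwise_calls(
        self, random_tree_factory, rng, metric
    ):
        tree = random_tree_factory(10, seed=23, prefix="asv")
        table = random_table(rng, n_samples=6, n_asvs=10)
        dm = bd.distance_matrix(table, tree, metric=metric)
        np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-15)
        fn = bd.weighted_unifrac if metric == "weighted_unifrac" else bd.unweighted_unifrac
        ids = list(table.columns)
        for i in range(6):
            for j in range(i + 1, 6):
                expected = fn(
                    table.iloc[i].to_numpy(), table.iloc[j].to_numpy(), ids, tree
                )
                assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)


class TestPermanova:
    def test_equidistant_design_gives_f_one(self):
        # all pairwise distances equal: R^2 = (a-1)/(N-1), F = 1
        n, a = 9, 3
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        labels = np.repeat(["x", "y", "z"], 3)
        res = bd.permanova(dm, labels, n_perm=99, seed=0)
        assert res.pseudo_F == pytest.approx(1.0, abs=1e-12)
        assert res.R2 == pytest.approx((a - 1) / (n - 1), abs=1e-12)

    def test_four_point_hand_computation(self):
        # two groups of 2, zero within, d between all cross pairs -> R^2 = 1
        d = 3.0
        m = np.array(
            [[0, 0, d, d], [0, 0, d, d], [d, d, 0, 0], [d, d, 0, 0]], dtype=float
        )
        dm = DistanceMatrix(m, ids=list("abcd"))
        labels = ["g1", "g1", "g2", "g2"]
        res = bd.permanova(dm, labels, n_perm=99, seed=0)
        f_oracle, r2_oracle = permanova_ss_oracle(m, labels)
        assert res.R2 == pytest.approx(r2_oracle, abs=1e-12)
        assert res.R2 == pytest.approx(1.0)

    def test_matches_ss_oracle_and_skbio_on_random_input(self, rng):
        x = rng.normal(size=(10, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(10)])
        labels = list(rng.permutation(["a"] * 5 + ["b"] * 5))
        res = bd.permanova(dm, labels, n_perm=99, seed=0)
        f_oracle, r2_oracle = permanova_ss_oracle(d, labels)
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-10)
        assert res.R2 == pytest.approx(r2_oracle, rel=1e-10)
        skbio_res = skbio_permanova(dm, labels, permutations=99)
        assert res.pseudo_F == pytest.approx(
            float(skbio_res["test statistic"]), rel=1e-8
        )

    def test_scale_invariance(self, rng):
        x = rng.normal(size=(8, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        labels = ["a"] * 4 + ["b"] * 4
        r1 = bd.permanova(DistanceMatrix(d, ids=list("abcdefgh")), labels,
                          n_perm=99, seed=1)
        r2 = bd.permanova(DistanceMatrix(7 * d, ids=list("abcdefgh")), labels,
                          n_perm=99, seed=1)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-12)
        assert r1.R2 == pytest.approx(r2.R2, rel=1e-12)
        assert r1.p == r2.p

    def test_single_group_is_error(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            bd.permanova(dm, ["a", "a", "a"], n_perm=99, seed=0)

    def test_p_never_below_one_over_nperm_plus_one(self, rng):
        x = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(10, 1, (5, 2))])
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(10)])
        res = bd.permanova(dm, ["a"] * 5 + ["b"] * 5, n_perm=199, seed=0)
        assert res.p >= 1 / 200


class TestBetaDispersion:
    def test_euclidean_centroid_distances_match_geometry(self, rng):
        x = rng.normal(size=(12, 2))
        labels = np.repeat(["a", "b"], 6)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        z = bd.centroid_distances(dm, labels)
        expected = np.empty(12)
        for g in ("a", "b"):
            idx = labels == g
            expected[idx] = np.linalg.norm(x[idx] - x[idx].mean(axis=0), axis=1)
        np.testing.assert_allclose(z, expected, atol=1e-8)

    def test_coincident_points_degenerate(self):
        dm = DistanceMatrix(np.zeros((6, 6)), ids=[f"s{i}" for i in range(6)])
        f, p = bd.beta_dispersion(dm, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert f == 0.0 and p == 1.0

    def test_equal_spread_groups_give_f_near_one(self, rng):
        fs = []
        for i in range(60):
            x = rng.normal(size=(16, 2))
            labels = np.repeat(["a", "b"], 8)
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(16)])
            z = bd.centroid_distances(dm, labels)
            f = stats.f_oneway(z[:8], z[8:]).statistic
            fs.append(f)
        # under exchangeability E[F] = df_w/(df_w-2) = 14/12, near 1
        assert 0.7 < np.mean(fs) < 1.7

    def test_singleton_group_excluded_with_warning(self, rng):
        x = rng.normal(size=(7, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(7)])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"]
        with pytest.warns(UserWarning, match="size-1"):
            f, p = bd.beta_dispersion(dm, labels, n_perm=99, seed=0)
        assert np.isfinite(f)
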