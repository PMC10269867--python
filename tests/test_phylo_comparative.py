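import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aviphylosym import phylo_comparative as pc, synthetic_data as sd
from aviphylosym.core_io import parse_newick
from oracles import vcv_oracle


class TestVcv:
    def test_star_tree_identity(self, star_tree):
        c = pc.vcv_from_tree(star_tree)
        np.testing.assert_allclose(c.to_numpy(), np.eye(8), atol=1e-12)

    def test_two_sisters_read_off_path_lengths(self):
        tree = parse_newick("((A:0.4,B:0.4):0.6,C:1.0);")
        c = pc.vcv_from_tree(tree, ["A", "B"])
        assert c.loc["A", "A"] == pytest.approx(1.0)
        assert c.loc["A", "B"] == pytest.approx(0.6)

    def test_matches_mrca_oracle_on_random_tree(self, random_tree_factory):
        tree = random_tree_factory(20, seed=31)
        c = pc.vcv_from_tree(tree)
        oracle = vcv_oracle(tree)
        for i in c.index:
            for j in c.columns:
                assert c.loc[i, j] == pytest.approx(oracle[(i, j)], abs=1e-10)

    def test_missing_species_is_error(self, star_tree):
        with pytest.raises(ValueError, match="absent"):
            pc.vcv_from_tree(star_tree, ["t0", "nope"])


class TestLambdaTransform:
    def setup_method(self):
        self.c = pd.DataFrame(
            [[1.0, 0.6], [0.6, 1.0]], index=["A", "B"], columns=["A", "B"]
        )

    def test_identity_at_one(self):
        pd.testing.assert_frame_equal(pc.lambda_transform(self.c, 1.0), self.c)

    def test_diagonal_at_zero(self):
        out = pc.lambda_transform(self.c, 0.0)
        np.testing.assert_allclose(out.to_numpy(), np.eye(2))

    def test_half(self):
        assert pc.lambda_transform(self.c, 0.5).loc["A", "B"] == pytest.approx(0.3)

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_out_of_range(self, lam):
        with pytest.raises(ValueError):
            pc.lambda_transform(self.c, lam)


class TestPagelLambda:
    def test_profiled_loglik_equals_mvn_logpdf(self, random_tree_factory):
        # the profiled likelihood must equal the exact MVN density at the
        # profiled parameters (independent check of the GLS algebra)
        tree = random_tree_factory(15, seed=41)
        trait = sd.simulate_trait_lambda(tree, 0.7, 1.0, 2.0, seed=3)
        c = pc.vcv_from_tree(tree, list(trait.index))
        y = trait.loc[c.index].to_numpy()
        v = pc.lambda_transform(c.to_numpy(), 0.7)
        ll, beta, sigma2, _ = pc._mvn_profile_loglik(y, np.ones((len(y), 1)), v)
        direct = stats.multivariate_normal.logpdf(
            y, mean=np.full(len(y), beta[0]), cov=sigma2 * v
        )
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_iid_trait_estimates_near_zero(self, random_tree_factory, rng):
        rejections, lams = 0, []
        for i in range(30):
            tree = random_tree_factory(100, seed=100 + i)
            species = [t.name for t in tree.tips()]
            trait = pd.Series(rng.normal(size=100), index=species)
            fit = pc.fit_pagel_lambda(trait, tree)
            lams.append(fit.lam)
            rejections += fit.p < 0.05
        assert np.mean(lams) < 0.15
        assert rejections / 30 <= 0.1 + 1e-9  # >=90% non-significant

    def test_bm_trait_estimates_near_one(self, random_tree_factory):
        lams = []
        for i in range(15):
            tree = random_tree_factory(150, seed=200 + i)
            trait = sd.simulate_trait_lambda(tree, 1.0, 0.0, 1.0, seed=i)
            lams.append(pc.fit_pagel_lambda(trait, tree).lam)
        assert abs(np.mean(lams) - 1.0) < 0.1

    def test_monotone_recovery_in_true_lambda(self, random_tree_factory):
        means = []
        for true_lam in (0.0, 0.5, 1.0):
            lams = []
            for i in range(10):
                tree = random_tree_factory(120, seed=300 + i)
                trait = sd.simulate_trait_lambda(tree, true_lam, 0.0, 1.0, seed=i)
                lams.append(pc.fit_pagel_lambda(trait, tree).lam)
            means.append(np.mean(lams))
        assert means[0] < means[1] < means[2]

    def test_star_tree_flat_likelihood_warns(self, star_tree, rng):
        trait = pd.Series(rng.normal(size=8), index=[f"t{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="flat"):
            fit = pc.fit_pagel_lambda(trait, star_tree)
        assert fit.lam == 0.0
        assert fit.flat

    def test_loglik_at_optimum_beats_boundaries(self, random_tree_factory):
        tree = random_tree_factory(60, seed=77)
        trait = sd.simulate_trait_lambda(tree, 0.5, 0.0, 1.0, seed=9)
        fit = pc.fit_pagel_lambda(trait, tree)
        c = pc.vcv_from_tree(tree, list(trait.index))
        y = trait.loc[c.index].to_numpy()
        ones = np.ones((len(y), 1))
        for lam in (0.0, 1.0):
            ll = pc._mvn_profile_loglik(
                y, ones, pc.lambda_transform(c.to_numpy(), lam)
            )[0]
            assert fit.loglik >= ll - 1e-8

    def test_constant_trait_and_tiny_trees_rejected(self, star_tree):
        const = pd.Series(1.0, index=[f"t{i}" for i in range(8)])
        with pytest.raises(ValueError):
            pc.fit_pagel_lambda(const, star_tree)
        small = pd.Series([1.0, 2.0, 3.0], index=["t0", "t1", "t2"])
        with pytest.raises(ValueError):
            pc.fit_pagel_lambda(small, star_tree)


class TestRegressions:
    def test_exact_linear_relation_gives_r_one(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        fit = pc.pearson_regression(x, 2 * x)
        assert fit.value == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_r_invariant_to_affine_rescaling(self, rng):
        idx = [f"t{i}" for i in range(20)]
        x = pd.Series(rng.normal(size=20), index=idx)
        y = pd.Series(rng.normal(size=20), index=idx)
        r1 = pc.pearson_regression(x, y).value
        r2 = pc.pearson_regression(3 * x + 7, y).value
        assert r1 == pytest.approx(r2)

    def test_null_p_values_roughly_uniform(self, rng):
        idx = [f"t{i}" for i in range(100)]
        ps = []
        for _ in range(100):
            x = pd.Series(rng.normal(size=100), index=idx)
            y = pd.Series(rng.normal(size=100), index=idx)
            ps.append(pc.pearson_regression(x, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_pgls_on_star_tree_equals_ols(self, star_tree, rng):
        idx = [f"t{i}" for i in range(8)]
        x = pd.Series(rng.normal(size=8), index=idx)
        y = pd.Series(2 * x + rng.normal(scale=0.3, size=8), index=idx)
        pgls = pc.pgls_fit(x, y, star_tree)
        ols = stats.linregress(x.loc[idx], y.loc[idx])
        assert pgls.slope == pytest.approx(ols.slope, abs=1e-8)
        assert pgls.p == pytest.approx(ols.pvalue, abs=1e-8)

    def test_pgls_recovers_slope_at_low_noise(self, random_tree_factory):
        tree = random_tree_factory(50, seed=55)
        mass, div = sd.simulate_mass_and_diversity(tree, 2.0, 1.0, 1e-4, seed=1)
        fit = pc.pgls_fit(np.log(mass), div, tree)
        assert fit.slope == pytest.approx(2.0, abs=1e-2)

    def test_pgls_lambda_ml_variant_runs(self, random_tree_factory):
        tree = random_tree_factory(40, seed=66)
        mass, div = sd.simulate_mass_and_diversity(tree, -0.05, 0.5, 0.2, seed=2)
        fit = pc.pgls_fit(np.log(mass), div, tree, correlation="lambda_ml")
        assert 0.0 <= fit.lam <= 1.0
        assert np.isfinite(fit.p)


class TestSubsetsAndBonferroni:
    def _meta(self, species, orders=None, sites=None):
        n = len(species)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "species": species,
                "order": orders or ["Passeriformes"] * n,
                "body_site": sites or ["blood"] * n,
            }
        ).set_index("sample_id", drop=False)

    def test_all_passeriformes_identity(self, star_tree):
        meta = self._meta([f"t{i}" for i in range(8)])
        species, pruned = pc.subset_species(meta, star_tree, "passeriformes")
        assert species == sorted(f"t{i}" for i in range(8))
        assert {t.name for t in pruned.tips()} == set(species)

    def test_n_gt_2_threshold_rule(self, star_tree):
        species = ["t0"] + ["t1"] * 2 + ["t2"] * 3 + ["t3"] * 4
        meta = self._meta(species)
        kept, pruned = pc.subset_species(meta, star_tree, "n_gt_2")
        assert kept == ["t2", "t3"]
        assert {t.name for t in pruned.tips()} == {"t2", "t3"}

    def test_empty_subset_is_error(self, star_tree):
        meta = self._meta(["t0"], orders=["OtherOrder"])
        with pytest.raises(ValueError):
            pc.subset_species(meta, star_tree, "passeriformes")

    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 4, 0.04), (0.5, 4, 1.0), (0.3, 1, 0.3)]
    )
    def test_bonferroni(self, p, m, expected):
        assert pc.bonferroni([p], m)[0] == pytest.approx(expected)


def test_comparative_report_structure(small_dataset):
    """The report covers every site x subset x metric cell with adjusted p's."""
    from aviphylosym import rarefaction_alpha as ra

    host, table, meta, asv_tree, config = small_dataset
    rarefied = ra.rarefy(table, 2000, seed=0)
    alpha = ra.alpha_diversity(rarefied, asv_tree)
    species_alpha = {}
    for site in config.body_sites:
        site_samples = meta.index[meta["body_site"] == site]
        sub = alpha[alpha["sample_id"].isin(site_samples)]
        species_alpha[site] = ra.aggregate_by_species(sub, meta)
    report = pc.comparative_report(
        species_alpha, meta, host, subsets=("full", "n_gt_2")
    )
    ok = report[report["status"] == "ok"]
    assert set(ok["body_site"]) == set(config.body_sites)
    assert set(ok["metric"]) == {"observed", "shannon", "simpson", "faith_pd"}
    assert (ok["lambda_"].between(0, 1)).all()
    assert (ok["r_p_raw_adj"] >= ok["r_p_raw"] - 1e-12).all()
    assert (ok["m"] == len(ok) / 2).all()  # two subsets share the block count
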