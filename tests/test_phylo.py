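"""Phylogenetic correlation structures and comparative GLS."""

import io

import dendropy
import numpy as np
import pandas as pd
import pytest

from floralhum import phylo, simulate


def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def star_tree(n, length=1.0):
    tips = ",".join(f"t{i}:{length}" for i in range(n))
    return tree_from_newick(f"({tips});")


class TestBuildCorrelation:
    def test_star_tree_bm_is_identity(self):
        corr, labels = phylo.build_correlation(star_tree(6), "BM")
        np.testing.assert_allclose(corr, np.eye(6), atol=1e-12)
        assert len(labels) == 6

    def test_sister_pair_shares_branch_fraction(self):
        # sisters split at 0.7 of total height 1.0 -> correlation 0.7
        t = tree_from_newick("((a:0.3,b:0.3):0.7,c:1.0);")
        corr, labels = phylo.build_correlation(t, "BM", taxa=["a", "b", "c"])
        assert corr[0, 1] == pytest.approx(0.7)
        assert corr[0, 2] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_ou_limit_recovers_bm(self):
        t = tree_from_newick(
            "(((a:0.2,b:0.2):0.3,c:0.5):0.5,(d:0.6,e:0.6):0.4);"
        )
        bm, _ = phylo.build_correlation(t, "BM", taxa=list("abcde"))
        ou, _ = phylo.build_correlation(t, "OU", alpha=1e-6,
                                        taxa=list("abcde"))
        np.testing.assert_allclose(ou, bm, atol=1e-4)

    def test_ou_decreases_with_patristic_distance(self):
        t = tree_from_newick(
            "(((a:0.2,b:0.2):0.3,c:0.5):0.5,(d:0.6,e:0.6):0.4);"
        )
        ou, _ = phylo.build_correlation(t, "OU", alpha=2.0,
                                        taxa=list("abcde"))
        # a-b (distance 0.4) closer than a-c (1.0) closer than a-d (2.0)
        assert ou[0, 1] > ou[0, 2] > ou[0, 3]

    def test_branch_rescaling_leaves_bm_unchanged(self):
        t1 = tree_from_newick("((a:0.3,b:0.3):0.7,c:1.0);")
        t2 = tree_from_newick("((a:3,b:3):7,c:10);")
        c1, _ = phylo.build_correlation(t1, "BM", taxa=["a", "b", "c"])
        c2, _ = phylo.build_correlation(t2, "BM", taxa=["a", "b", "c"])
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_invalid_inputs(self):
        t = star_tree(4)
        with pytest.raises(phylo.PhyloError, match="alpha"):
            phylo.build_correlation(t, "OU", alpha=-1.0)
        with pytest.raises(phylo.PhyloError, match="unknown"):
            phylo.build_correlation(t, "lambda")
        with pytest.raises(phylo.PhyloError, match="absent"):
            phylo.build_correlation(t, "BM", taxa=["nope"])


def make_traits(n, seed=0, response=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "species": [f"t{i}" for i in range(n)],
        "response": (rng.normal(size=n) if response is None else response),
        "span": rng.lognormal(np.log(35), 0.4, n),
        "floral_type": rng.integers(0, 2, n),
        "grown_outside": rng.integers(0, 2, n),
    })
    return df


class TestPGLSFit:
    def test_star_tree_equals_ols(self):
        n = 20
        traits = make_traits(n, seed=1)
        fit = phylo.pgls_fit(traits, star_tree(n), "BM")
        X = np.column_stack([
            np.ones(n), traits.span, traits.floral_type, traits.grown_outside,
        ])
        beta = np.linalg.lstsq(X, traits.response.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)

    def test_bm_recovery_unbiased(self):
        errs = []
        for s in range(60):
            tree, table, _ = simulate.generate_phylo_dataset(
                40, {"span": 0.01}, seed=500 + s)
            fit = phylo.pgls_fit(table, tree, "BM")
            errs.append(fit.coefficients[1] - 0.01)
        mc_se = np.std(errs) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 3 * mc_se + 1e-4

    def test_alpha_profile_invariant_to_response_shift(self):
        tree, table, _ = simulate.generate_phylo_dataset(
            20, {"span": 0.01}, correlation_model="OU", alpha=2.0, seed=9)
        f1 = phylo.pgls_fit(table, tree, "OU", estimate_alpha=True)
        shifted = table.copy()
        shifted["response"] = shifted["response"] + 7.5
        f2 = phylo.pgls_fit(shifted, tree, "OU", estimate_alpha=True)
        assert f2.alpha == pytest.approx(f1.alpha, rel=1e-3)
        assert f2.coefficients[0] == pytest.approx(
            f1.coefficients[0] + 7.5, abs=1e-6)

    def test_collinear_predictors_rejected(self):
        traits = make_traits(15, seed=2)
        traits["dup"] = traits["span"]
        with pytest.raises(phylo.PhyloError, match="collinear"):
            phylo.pgls_fit(traits, star_tree(15), "BM",
                           predictors=("span", "dup"))

    def test_too_few_species_rejected(self):
        with pytest.raises(phylo.PhyloError, match="2 more species"):
            phylo.pgls_fit(make_traits(5), star_tree(5), "BM")

    def test_aic_counts_alpha_when_estimated(self):
        tree, table, _ = simulate.generate_phylo_dataset(
            15, {}, seed=4)
        bm = phylo.pgls_fit(table, tree, "BM")
        ou_fixed = phylo.pgls_fit(table, tree, "OU", alpha=1.0)
        ou_est = phylo.pgls_fit(table, tree, "OU", estimate_alpha=True)
        k_bm = (bm.aic + 2 * bm.log_likelihood) / 2
        k_fixed = (ou_fixed.aic + 2 * ou_fixed.log_likelihood) / 2
        k_est = (ou_est.aic + 2 * ou_est.log_likelihood) / 2
        # 4 coefficients + residual variance (+ alpha when estimated)
        assert k_bm == pytest.approx(5)
        assert k_fixed == pytest.approx(5)
        assert k_est == pytest.approx(6)


class TestPrepareTraits:
    def test_labels_coded_and_logged(self):
        df = pd.DataFrame({
            "species": ["a", "b", "c"],
            "delta_rh_max": [0.5, 1.0, 2.0],
            "span": [10.0, 20.0, 30.0],
            "floral_type": ["flower", "inflorescence", "flower"],
            "grown_outside": [1, 0, 1],
        })
        out = phylo.prepare_traits(df)
        np.testing.assert_allclose(out["response"],
                                   np.log([0.5, 1.0, 2.0]))
        assert out["floral_type"].tolist() == [0, 1, 0]

    def test_nonpositive_response_rejected(self):
        df = pd.DataFrame({
            "species": ["a", "b"], "delta_rh_max": [0.0, 1.0],
            "span": [1.0, 2.0], "floral_type": [0, 1],
            "grown_outside": [0, 1],
        })
        with pytest.raises(phylo.PhyloError, match="log-transform"):
            phylo.prepare_traits(df)


class TestCompareModels:
    def test_identical_fits_give_zero(self):
        tree, table, _ = simulate.generate_phylo_dataset(12, {}, seed=6)
        fit = phylo.pgls_fit(table, tree, "BM")
        cmp_ = phylo.compare_models(fit, fit, nested=True)
        assert cmp_.delta_aic == 0.0
        assert cmp_.lr_statistic == 0.0

    def test_lr_matches_direct_likelihood_oracle(self):
        # identity correlation: both fits are OLS; evaluate profiled
        # Gaussian likelihoods directly
        n = 25
        traits = make_traits(n, seed=7)
        tree = star_tree(n)
        full = phylo.pgls_fit(traits, tree, "BM")
        null = phylo.pgls_fit(traits, tree, "BM", predictors=())
        y = traits.response.to_numpy()
        X = np.column_stack([np.ones(n), traits.span, traits.floral_type,
                             traits.grown_outside])

        def profiled_ll(X_):
            beta = np.linalg.lstsq(X_, y, rcond=None)[0]
            rss = float(np.sum((y - X_ @ beta) ** 2))
            s2 = rss / n
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

        oracle = 2 * (profiled_ll(X) - profiled_ll(np.ones((n, 1))))
        cmp_ = phylo.compare_models(full, null, nested=True)
        assert cmp_.lr_statistic == pytest.approx(oracle, abs=1e-8)
        assert cmp_.df == 3

    def test_mismatched_species_rejected(self):
        t1, tb1, _ = simulate.generate_phylo_dataset(12, {}, seed=8)
        t2, tb2, _ = simulate.generate_phylo_dataset(14, {}, seed=8)
        f1 = phylo.pgls_fit(tb1, t1, "BM")
        f2 = phylo.pgls_fit(tb2, t2, "BM")
        with pytest.raises(phylo.PhyloError, match="species"):
            phylo.compare_models(f1, f2)
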