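"""Conditional logistic fitting, control selection, and the matched designs."""

import numpy as np
import pandas as pd
import pytest

from titans import expression_models as em
from titans import matched_analysis as ma
from titans import trio_genotypes as tg


class TestSelectControls:
    def test_exact_match_removed(self):
        controls, excl = ma.select_controls(1.0, [1.0, 0.5, 0.2, 0.9])
        assert excl == 0 and sorted(controls) == [0.2, 0.5, 0.9]

    def test_tie_removes_lowest_index(self):
        controls, excl = ma.select_controls(1.0, [1.0, 1.0, 0.2, 0.9])
        assert excl == 0 and sorted(controls) == [0.2, 0.9, 1.0]

    def test_multivariate_ssq(self):
        configs = [(1, 0), (0, 0), (1, 1), (2, 0)]
        controls, excl = ma.select_controls(np.array([1.0, 0.0]), configs,
                                            mode="multivariate")
        assert excl == 0
        assert {tuple(c) for c in controls} == {(0, 0), (1, 1), (2, 0)}

    def test_exactly_four_required(self):
        with pytest.raises(ValueError, match="4"):
            ma.select_controls(0.0, [1.0, 2.0, 3.0])


def sim_exposures(n, k=3, seed=0, beta=0.8):
    """Matched sets with a known transmission effect, by direct sampling."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k + 1))
    # make column 0 the case by conditional-logistic resampling
    w = np.exp(beta * X)
    pick = np.array([rng.choice(k + 1, p=wi / wi.sum()) for wi in w])
    X[np.arange(n), [0] * n], X[np.arange(n), pick] = X[np.arange(n), pick], X[np.arange(n), [0] * n]
    return X


class TestConditionalLogistic:
    @pytest.mark.parametrize("k", [3, 2])
    def test_null_loglik_identity(self, k):
        X = sim_exposures(17, k=k, seed=1, beta=0.0)
        ll0 = ma._loglik(ma._prepare(X), np.zeros(1))
        assert ll0 == pytest.approx(-17 * np.log(k + 1), abs=1e-12)

    def test_grid_search_oracle(self):
        """beta-hat and SE match a fine grid search + numerical Hessian."""
        X = sim_exposures(30, seed=2, beta=0.6)
        fit = ma.fit_conditional_logistic(X)
        grid = np.arange(-5, 5, 1e-4)
        Xp = ma._prepare(X)
        lls = np.array([ma._loglik(Xp, np.array([b])) for b in grid])
        beta_oracle = grid[lls.argmax()]
        assert abs(fit.beta - beta_oracle) <= 1e-3
        f = lambda b: ma._loglik(Xp, b)
        eps = 1e-5
        hess = (f(np.array([fit.beta + eps])) - 2 * f(np.array([fit.beta]))
                + f(np.array([fit.beta - eps]))) / eps**2
        se_oracle = 1 / np.sqrt(-hess)
        assert abs(fit.se - se_oracle) <= 1e-3

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        X = sim_exposures(40, seed=3, beta=0.4)
        fit = ma.fit_conditional_logistic(X)
        n, m = X.shape
        y = np.tile([1] + [0] * (m - 1), n)
        res = ConditionalLogit(y, X.ravel()[:, None],
                               groups=np.repeat(np.arange(n), m)).fit(disp=False)
        # statsmodels' optimizer stops at a looser gradient tolerance
        assert fit.beta == pytest.approx(res.params[0], abs=1e-4)
        assert fit.se == pytest.approx(res.bse[0], abs=1e-4)

    def test_uninformative_sets_dropped(self):
        X = sim_exposures(10, seed=4, beta=0.0)
        X[3:] = 0.7  # identical members contribute a constant
        fit = ma.fit_conditional_logistic(X)
        assert fit.n_families_total == 10
        assert fit.n_families_informative == 3

    def test_all_uninformative_gives_na(self):
        fit = ma.fit_conditional_logistic(np.ones((5, 4)))
        assert np.isnan(fit.p) and fit.method == "none"

    def test_separation_detected(self):
        fit = ma.fit_conditional_logistic(np.array([[1.0, 0.0, 0.0, 0.0]]))
        assert fit.separation_flag and fit.method == "score"
        assert abs(fit.beta) == 15.0

    def test_within_family_shift_invariance(self):
        X = sim_exposures(25, seed=5, beta=0.5)
        shifts = np.random.default_rng(0).normal(size=(25, 1))
        fit1 = ma.fit_conditional_logistic(X)
        fit2 = ma.fit_conditional_logistic(X + shifts)
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-8)
        assert fit1.z == pytest.approx(fit2.z, abs=1e-6)

    def test_score_test_null_matches_wald_direction(self):
        X = sim_exposures(50, seed=6, beta=0.5)
        z, p = ma.score_test(X)
        fit = ma.fit_conditional_logistic(X)
        assert np.sign(z) == np.sign(fit.z)
        assert 0 < p <= 1


class TestOneSiblingAndParentDesigns:
    def test_matched_pairs_closed_form(self):
        """1:1 conditional MLE with binary exposure is log(n10/n01)."""
        # 12 discordant pairs case-exposed, 4 the reverse, 6 concordant
        X = np.array([[1.0, 0.0]] * 12 + [[0.0, 1.0]] * 4 + [[1.0, 1.0]] * 6)
        fit = ma.fit_one_sibling(X[:, 0], X[:, 1], regression_mode="conditional")
        assert fit.beta == pytest.approx(np.log(12 / 4), abs=1e-6)
        assert fit.n_families_informative == 16

    def test_identical_exposures_beta_zero(self):
        x = np.random.default_rng(1).normal(size=30)
        fit = ma.fit_one_sibling(x, x.copy(), regression_mode="conditional")
        assert np.isnan(fit.p)  # no informative pairs

    def test_unconditional_glm_recovers_effect(self):
        rng = np.random.default_rng(2)
        xp = rng.normal(loc=0.8, size=300)
        xs = rng.normal(loc=0.0, size=300)
        fit = ma.fit_one_sibling(xp, xs)
        assert fit.method == "wald" and fit.p < 1e-6 and fit.beta > 0

    def test_parent_control_null_loglik(self):
        rng = np.random.default_rng(3)
        fit = ma.fit_parent_control(rng.normal(size=20), rng.normal(size=20),
                                    rng.normal(size=20))
        X = np.column_stack([rng.normal(size=20)] * 1)  # unused; identity below
        assert fit.n_families_total == 20
        # beta=0 log-likelihood is -N ln 3 for K=2
        Xp = ma._prepare(np.column_stack([np.zeros(20), np.ones(20), 2 * np.ones(20)]))
        assert ma._loglik(Xp, np.zeros(1)) == pytest.approx(-20 * np.log(3), abs=1e-12)


class TestTwasPipeline:
    def test_causal_gene_detected_nulls_not(self, small_dataset):
        ds = small_dataset
        res = ma.run_twas(ds.matrix, ds.trios, ds.models)
        res = res.set_index("gene")
        assert res.loc["GENE1", "p"] < 0.05
        assert res.loc["GENE1", "beta"] > 0
        assert (res["n_informative"] > 0).all()

    def test_zero_variance_gene_is_na(self, small_dataset):
        ds = small_dataset
        # monomorphic predictor: all dosages identical across members
        preds = pd.DataFrame({"chrom": "1", "pos": [1], "ref": "A", "alt": "G",
                              "effect_allele": ["G"], "weight": [0.0001]})
        model = em.ExpressionModel("GMONO", "sim_tissue", predictors=preds)
        mono = ds.matrix.haplotypes.copy()
        mono[:, 0, :] = 1
        matrix = tg.PhasedGenotypeMatrix(ds.matrix.variants, ds.matrix.samples, mono)
        res = ma.run_twas(matrix, ds.trios, [model])
        assert res.reason.iloc[0] == "uninformative"
        assert np.isnan(res.p.iloc[0])

    def test_single_snp_twas_equals_gwas_z(self, small_dataset):
        ds = small_dataset
        v = ds.matrix.variants[0]
        preds = pd.DataFrame({"chrom": [v.chrom], "pos": [v.pos], "ref": [v.ref],
                              "alt": [v.alt], "effect_allele": [v.alt], "weight": [1.0]})
        model = em.ExpressionModel("GSNP", "sim_tissue", predictors=preds)
        twas = ma.run_twas(ds.matrix, ds.trios, [model])
        gwas = ma.run_trio_gwas(ds.matrix, ds.trios)
        z_twas = twas.z.iloc[0]
        z_gwas = gwas.set_index("pos").loc[v.pos, "z"]
        assert z_twas == pytest.approx(z_gwas, abs=1e-6)

    def test_gwas_monomorphic_variant_na(self, small_dataset):
        ds = small_dataset
        haps = ds.matrix.haplotypes.copy()
        haps[:, 1, :] = 0
        matrix = tg.PhasedGenotypeMatrix(ds.matrix.variants, ds.matrix.samples, haps)
        res = ma.run_trio_gwas(matrix, ds.trios)
        row = res[res.pos == matrix.variants[1].pos].iloc[0]
        assert row.reason == "monomorphic_in_parents"
        assert np.isnan(row.p)


class TestStratified:
    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            ma.stratified_twas(np.zeros((4, 4)), np.array([0, 0, 1, 1]),
                               n_permutations=0)

    def test_duplicated_groups_ratio_one(self):
        X = sim_exposures(30, seed=7, beta=0.7)
        Xdup = np.vstack([X, X])
        labels = np.array([0] * 30 + [1] * 30)
        res = ma.stratified_twas(Xdup, labels, n_permutations=20, seed=0)
        assert res["ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_no_interaction_p_not_extreme(self):
        X = sim_exposures(60, seed=8, beta=0.6)
        labels = np.array([0, 1] * 30)
        res = ma.stratified_twas(X, labels, n_permutations=99, seed=1)
        assert 1 / 100 <= res["permutation_p"] <= 1.0


class TestFineMapping:
    def test_single_model_reduces_to_univariate(self, small_dataset):
        ds = small_dataset
        fit, table = ma.conditional_fine_mapping(ds.matrix, ds.trios, ds.models[:1])
        uni = ma.run_twas(ds.matrix, ds.trios, ds.models[:1]).iloc[0]
        assert table.beta.iloc[0] == pytest.approx(uni.beta, abs=1e-6)
        assert table.p.iloc[0] == pytest.approx(uni.p, abs=1e-6)

    def test_duplicate_gene_collinearity_warning(self, small_dataset):
        ds = small_dataset
        import warnings as w

        with w.catch_warnings(record=True) as rec:
            w.simplefilter("always")
            fit, _ = ma.conditional_fine_mapping(ds.matrix, ds.trios,
                                                 [ds.models[0], ds.models[0]])
        assert fit.collinearity_flag or fit.separation_flag
        assert any("ridge" in str(r.message) or "singular" in str(r.message)
                   for r in rec)

    def test_causal_gene_survives_conditioning(self, small_dataset):
        ds = small_dataset
        fit, table = ma.conditional_fine_mapping(ds.matrix, ds.trios, ds.models[:2])
        table = table.set_index("gene")
        assert table.loc["GENE1", "p"] < table.loc["GENE2", "p"]
        assert table.loc["GENE1", "p"] < 0.05

    def test_mixed_tissue_rejected(self, small_dataset):
        ds = small_dataset
        other = em.ExpressionModel("GX", "other_tissue",
                                   predictors=ds.models[0].predictors)
        with pytest.raises(ValueError, match="tissue"):
            ma.conditional_fine_mapping(ds.matrix, ds.trios, [ds.models[0], other])
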