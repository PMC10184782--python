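"""Tree covariance, PGLS, phylogenetic logistic, ordinal, and PC regression."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from genomerisk import phylo_stats as ps, synthetic_cohort as syn
from genomerisk.errors import InvalidParameterError, RankDeficiencyError


def get_tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestTreeToCovariance:
    def test_star_tree(self):
        t = get_tree("(A:2,B:2,C:2,D:2);")
        cov = ps.tree_to_covariance(t)
        assert np.allclose(cov.matrix, 2 * np.eye(4))

    def test_three_tip_hand_case(self):
        t = get_tree("((A:1,B:1):1,C:2);")
        cov = ps.tree_to_covariance(t)
        i = {l: k for k, l in enumerate(cov.labels)}
        m = cov.matrix
        assert m[i["A"], i["B"]] == pytest.approx(1.0)
        assert m[i["A"], i["C"]] == pytest.approx(0.0)
        assert np.allclose(np.diag(m), 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_against_pairwise_path_oracle(self, seed):
        """Independent oracle: shared path length via per-pair MRCA walks."""
        tree = syn.generate_tree(10, 1.0, seed=seed)
        cov = ps.tree_to_covariance(tree)
        pdm = {}
        leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}

        def root_path(node):
            path = []
            while node is not None:
                path.append(node)
                node = node.parent_node
            return path[::-1]

        for a in cov.labels:
            for b in cov.labels:
                pa, pb = root_path(leaves[a]), root_path(leaves[b])
                shared = 0.0
                for x, y in zip(pa[1:], pb[1:]):  # skip root
                    if x is y:
                        shared += x.edge.length
                    else:
                        break
                pdm[(a, b)] = shared
        for i, a in enumerate(cov.labels):
            for j, b in enumerate(cov.labels):
                if i != j:
                    assert cov.matrix[i, j] == pytest.approx(pdm[(a, b)], abs=1e-9)

    def test_psd_and_symmetry(self, tree50):
        cov = ps.tree_to_covariance(tree50)
        assert np.allclose(cov.matrix, cov.matrix.T)
        assert np.linalg.eigvalsh(cov.matrix).min() > -1e-9
        off = cov.matrix - np.diag(np.diag(cov.matrix))
        assert (off.max(axis=1) <= np.diag(cov.matrix) + 1e-12).all()


class TestFitPgls:
    def test_star_tree_equals_ols_any_lambda(self, rng):
        n = 40
        c = 2.0 * np.eye(n)
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + 0.3 * rng.standard_normal(n)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        for lam in (0.0, 0.5, 1.0, "ML"):
            fit = ps.fit_pgls(pd.DataFrame({"x": x}), y, c, lambda_mode=lam)
            assert np.allclose(fit.coef, ols.params, atol=1e-8)
            assert np.allclose(fit.se, ols.bse, atol=1e-8)

    def test_lambda_zero_equals_ols_on_ultrametric_tree(self, tree50, rng):
        cov = ps.tree_to_covariance(tree50)
        n = len(cov.labels)
        x = rng.standard_normal(n)
        y = 0.3 - 0.7 * x + rng.standard_normal(n)
        fit = ps.fit_pgls(pd.DataFrame({"x": x}), y, cov, lambda_mode=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.allclose(fit.coef, ols.params, atol=1e-8)

    def test_dense_algebra_oracle(self, rng):
        """beta matches an independent full-matrix-inverse GLS at n=10."""
        tree = syn.generate_tree(10, 1.0, seed=8)
        cov = ps.tree_to_covariance(tree)
        n = 10
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        lam = 0.6
        fit = ps.fit_pgls(x[:, 1:], y, cov, lambda_mode=lam)
        v = lam * cov.matrix + (1 - lam) * np.diag(np.diag(cov.matrix))
        vinv = np.linalg.inv(v)
        beta = np.linalg.inv(x.T @ vinv @ x) @ x.T @ vinv @ y
        assert np.allclose(fit.coef, beta, atol=1e-6)

    def test_profile_optimality(self, tree50, rng):
        cov = ps.tree_to_covariance(tree50)
        n = len(cov.labels)
        chol = np.linalg.cholesky(cov.normalized() + 1e-12 * np.eye(n))
        x = rng.standard_normal(n)
        y = 0.5 * x + chol @ rng.standard_normal(n)
        fit = ps.fit_pgls(pd.DataFrame({"x": x}), y, cov)
        for lam in (0.0, 1.0):
            assert fit.loglik >= ps.pgls_loglik_at(
                pd.DataFrame({"x": x}), y, cov, lam) - 1e-6

    def test_tip_reordering_invariance(self, tree50, rng):
        cov = ps.tree_to_covariance(tree50)
        n = len(cov.labels)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        fit = ps.fit_pgls(pd.DataFrame({"x": x}), y, cov, lambda_mode=0.7)
        perm = rng.permutation(n)
        cov2 = ps.PhyloCovariance(
            labels=tuple(np.array(cov.labels)[perm]),
            matrix=cov.matrix[np.ix_(perm, perm)], scale=cov.scale)
        fit2 = ps.fit_pgls(pd.DataFrame({"x": x[perm]}), y[perm], cov2, lambda_mode=0.7)
        assert np.allclose(fit.coef, fit2.coef, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        n = 30
        x = rng.standard_normal(n)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficiencyError, match="aliased"):
            ps.fit_pgls(df, rng.standard_normal(n), np.eye(n))

    def test_bm_slope_recovery_small(self):
        """Parameter recovery at reduced scale (full scale in acceptance)."""
        tree = syn.generate_tree(100, 1.0, seed=12)
        cov = ps.tree_to_covariance(tree)
        cn = cov.normalized()
        n = 100
        chol = np.linalg.cholesky(cn + 1e-12 * np.eye(n))
        rng = np.random.default_rng(0)
        est = []
        for _ in range(100):
            x = chol @ rng.standard_normal(n)
            y = -0.5 * x + 0.5 * (chol @ rng.standard_normal(n))
            fit = ps.fit_pgls(pd.DataFrame({"x": x}), y, cov)
            est.append(fit.coef[1])
        assert np.mean(est) == pytest.approx(-0.5, abs=0.05)


class TestPhyloLogistic:
    def test_star_tree_matches_plain_firth(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + x)))).astype(float)
        fit = ps.fit_phylo_logistic(pd.DataFrame({"x": x}), y, np.eye(n), n_boot=0)
        xmat = np.column_stack([np.ones(n), x])
        beta, se = ps._firth_logistic(xmat, y)
        assert np.allclose(fit.coef, beta, atol=1e-6)
        # sanity: close to unpenalized MLE at this n
        mle = sm.Logit(y, xmat).fit(disp=0)
        assert np.allclose(fit.coef, mle.params, atol=0.1)

    def test_separation_is_finite(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        fit = ps.fit_phylo_logistic(pd.DataFrame({"x": x}), y, np.eye(40), n_boot=0)
        assert np.all(np.isfinite(fit.coef)) and np.all(np.isfinite(fit.se))

    def test_constant_response_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.fit_phylo_logistic(
                pd.DataFrame({"x": np.arange(20.0)}), np.ones(20), np.eye(20))

    def test_power_with_strong_effect(self):
        """Planted liability effect detected at n = 200 in most replicates."""
        rejections = 0
        reps = 10
        for s in range(reps):
            tree = syn.generate_tree(200, 1.0, seed=300 + s)
            cov = ps.tree_to_covariance(tree)
            cn = cov.normalized()
            chol = np.linalg.cholesky(cn + 1e-12 * np.eye(200))
            rng = np.random.default_rng(s)
            x = chol @ rng.standard_normal(200)
            liab = 2.0 * x + chol @ rng.standard_normal(200)
            y = (liab > np.quantile(liab, 0.65)).astype(float)
            fit = ps.fit_phylo_logistic(
                pd.DataFrame({"x": x}), y, cov, n_boot=99, seed=s)
            rejections += fit.p_boot[1] < 0.05
        assert rejections >= 0.8 * reps

    def test_bootstrap_determinism(self, rng):
        n = 60
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(float)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        a = ps.fit_phylo_logistic(pd.DataFrame({"x": x}), y, np.eye(n), n_boot=50, seed=3)
        b = ps.fit_phylo_logistic(pd.DataFrame({"x": x}), y, np.eye(n), n_boot=50, seed=3)
        assert np.array_equal(a.p_boot, b.p_boot)


class TestOrdinal:
    def test_two_categories_collapse_to_logistic(self, rng):
        x = rng.standard_normal(300)
        y = np.where(rng.random(300) < 1 / (1 + np.exp(-0.5 * x)), "NT", "LC")
        fit = ps.fit_ordinal(pd.DataFrame({"x": x}), y)
        logit = sm.Logit((y == "NT").astype(float), sm.add_constant(x)).fit(disp=0, tol=1e-12)
        assert fit.coef[0] == pytest.approx(logit.params[1], abs=1e-6)
        assert -fit.cutpoints[0] == pytest.approx(logit.params[0], abs=1e-6)

    def test_probabilities_sum_to_one(self, cohort50):
        f = cohort50.features
        x = pd.DataFrame({"log_ne": np.log(f.ne_harmonic.to_numpy())})
        fit = ps.fit_ordinal(x, f.iucn)
        assert np.allclose(fit.probs.sum(axis=1), 1.0, atol=1e-10)
        assert list(fit.probs.columns) == list(ps.IUCN_ORDER)

    def test_cutpoints_increase(self, cohort50):
        f = cohort50.features
        x = pd.DataFrame({"log_ne": np.log(f.ne_harmonic.to_numpy())})
        fit = ps.fit_ordinal(x, f.iucn)
        assert np.all(np.diff(fit.cutpoints) > 0)

    def test_proportional_odds_slope_recovery(self):
        """Data from a proportional-odds model return the generating slope."""
        rng = np.random.default_rng(7)
        cuts = np.array([-1.0, 0.0, 1.0, 2.0])
        slope = 0.8
        est = []
        for _ in range(40):
            x = rng.standard_normal(500)
            u = rng.logistic(size=500)
            latent = slope * x + u
            yk = np.searchsorted(cuts, latent)
            y = np.array(ps.IUCN_ORDER)[yk]
            if len(set(y)) < 2:
                continue
            fit = ps.fit_ordinal(pd.DataFrame({"x": x}), y)
            est.append(fit.coef[0])
        assert np.mean(est) == pytest.approx(slope, rel=0.1)


class TestPcRegression:
    def test_orthonormal_loadings_and_ordered_variance(self, cohort50):
        f = cohort50.features
        y = f.threatened.astype(float).to_numpy()
        fit = ps.pc_regression(f[list(syn.SUMMARY_COLUMNS)], y, n_components=3)
        k = fit.loadings.shape[1]
        assert np.allclose(fit.loadings.T @ fit.loadings, np.eye(k), atol=1e-8)
        assert np.all(np.diff(fit.explained_variance) <= 1e-9)

    def test_median_imputation_handles_missing(self, cohort50):
        f = cohort50.features.copy()
        cols = list(syn.SUMMARY_COLUMNS)
        f.loc[f.index[:5], cols[0]] = np.nan
        y = f.threatened.astype(float).to_numpy()
        fit = ps.pc_regression(f[cols], y, n_components=2)
        assert np.all(np.isfinite(fit.scores))

    def test_planted_factor_carries_signal(self):
        """With outcome signal on one latent factor, PC1 is the significant
        predictor in the large majority of replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 30
        for _ in range(reps):
            n, p = 150, 10
            factor = rng.standard_normal(n)
            feats = pd.DataFrame(
                {f"f{j}": factor + 0.4 * rng.standard_normal(n) for j in range(p)})
            y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * factor))).astype(float)
            fit = ps.pc_regression(feats, y, n_components=3)
            pv = fit.glm.pvalues[1:]
            if pv[0] < 0.05 and pv[0] == pv.min():
                hits += 1
        assert hits >= 0.9 * reps


class TestModelError:
    def test_perfect_predictor_zero_error(self, rng):
        y = rng.integers(0, 2, 200)
        x = pd.DataFrame({"x": y.astype(float)})
        rep = ps.regression_model_error(ps.default_logistic_factory, x, y, n_runs=10, seed=0)
        assert rep.mean_misclassification == 0.0

    def test_permuted_labels_at_baseline(self, rng):
        n = 300
        x = pd.DataFrame({"x": rng.standard_normal(n)})
        y = rng.permutation(np.repeat([0, 1], n // 2))
        rep = ps.regression_model_error(ps.default_logistic_factory, x, y, n_runs=20, seed=1)
        assert abs(rep.mean_misclassification - 0.5) < 0.1

    def test_identical_seed_identical_errors(self, rng):
        n = 100
        x = pd.DataFrame({"x": rng.standard_normal(n)})
        y = (rng.random(n) < 0.4).astype(int)
        a = ps.regression_model_error(ps.default_logistic_factory, x, y, n_runs=5, seed=2)
        b = ps.regression_model_error(ps.default_logistic_factory, x, y, n_runs=5, seed=2)
        pd.testing.assert_frame_equal(a.per_run, b.per_run)
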