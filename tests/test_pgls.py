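"""Phylogenetic covariance construction, GLS fitting, and λ profiling."""

import dendropy
import numpy as np
import pytest

from bmrscale import (
    DataValidationError,
    InsufficientDataError,
    SpeciesRecord,
    fit_ols,
    gls_fit,
    lambda_transform,
    pgls_allometry,
    profile_lambda_ml,
    prune_and_match,
    simulate_bm_lambda,
    simulate_yule_tree,
    vcv_from_tree,
)
from bmrscale.pgls import PhyloCovariance, normalize_label

from conftest import make_records, tree_from_newick


class TestVCV:
    def test_two_tip_tree_is_diagonal(self):
        C = vcv_from_tree(tree_from_newick("(A:1,B:1);"))
        np.testing.assert_allclose(C.matrix, np.eye(2))

    def test_three_tip_hand_worked(self, three_tip_tree):
        C = vcv_from_tree(three_tip_tree)
        m = {t: i for i, t in enumerate(C.tip_order)}
        assert C.matrix.diagonal().tolist() == [2.0, 2.0, 2.0]
        assert C.matrix[m["A"], m["B"]] == 1.0
        assert C.matrix[m["A"], m["C"]] == 0.0
        assert C.matrix[m["B"], m["C"]] == 0.0

    def test_star_tree_is_identity_times_depth(self):
        C = vcv_from_tree(tree_from_newick("(A:3,B:3,C:3,D:3);"))
        np.testing.assert_allclose(C.matrix, 3.0 * np.eye(4))

    def test_unrooted_tree_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        tree.is_rooted = False
        with pytest.raises(DataValidationError, match="root"):
            vcv_from_tree(tree)

    def test_offdiag_bounded_by_diag(self, rng):
        tree = simulate_yule_tree(25, rng)
        C = vcv_from_tree(tree).matrix
        d = C.diagonal()
        bound = np.minimum.outer(d, d)
        assert np.all(C <= bound + 1e-12)
        np.testing.assert_allclose(C, C.T)


class TestLambdaTransform:
    def test_identity_at_one(self, three_tip_tree):
        C = vcv_from_tree(three_tip_tree)
        np.testing.assert_array_equal(lambda_transform(C, 1.0).matrix, C.matrix)

    def test_diagonal_at_zero(self, three_tip_tree):
        C = lambda_transform(vcv_from_tree(three_tip_tree), 0.0)
        np.testing.assert_allclose(C.matrix, np.diag(C.matrix.diagonal()))

    def test_half(self, three_tip_tree):
        C = lambda_transform(vcv_from_tree(three_tip_tree), 0.5)
        m = {t: i for i, t in enumerate(C.tip_order)}
        assert C.matrix[m["A"], m["B"]] == 0.5
        assert C.matrix.diagonal().tolist() == [2.0, 2.0, 2.0]

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_domain(self, three_tip_tree, lam):
        with pytest.raises(ValueError):
            lambda_transform(vcv_from_tree(three_tip_tree), lam)


def _random_cov(rng, n):
    tree = simulate_yule_tree(n, rng)
    return lambda_transform(vcv_from_tree(tree), rng.uniform(0.2, 1.0))


class TestGLS:
    def test_identity_covariance_equals_ols(self, rng):
        n = 20
        x = rng.uniform(0, 3, n)
        y = 0.5 + 0.7 * x + rng.normal(0, 0.1, n)
        C = PhyloCovariance([f"t{i}" for i in range(n)], np.eye(n))
        res = gls_fit(x, y, C)
        ols = fit_ols(x, y)
        assert res.slope == pytest.approx(ols.b, abs=1e-10)
        assert res.intercept == pytest.approx(ols.intercept_log10, abs=1e-10)
        assert res.se_slope == pytest.approx(ols.se_b, abs=1e-10)

    def test_matches_textbook_inverse_oracle(self, rng):
        n = 15
        C = _random_cov(rng, n)
        x = rng.uniform(0, 3, n)
        y = 0.5 + 0.7 * x + rng.normal(0, 0.3, n)
        X = np.column_stack([np.ones(n), x])
        Ci = np.linalg.inv(C.matrix)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        res = gls_fit(x, y, C)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_matches_statsmodels_gls(self, rng):
        import statsmodels.api as sm

        n = 12
        C = _random_cov(rng, n)
        x = rng.uniform(0, 3, n)
        y = 0.5 + 0.7 * x + rng.normal(0, 0.3, n)
        res = gls_fit(x, y, C)
        smres = sm.GLS(y, sm.add_constant(x), sigma=C.matrix).fit()
        assert res.slope == pytest.approx(smres.params[1], rel=1e-8)
        assert res.se_slope == pytest.approx(smres.bse[1], rel=1e-8)

    def test_exact_line_interpolates(self, rng):
        n = 10
        C = _random_cov(rng, n)
        x = rng.uniform(0, 3, n)
        y = 2.0 * x + 1.0
        res = gls_fit(x, y, C)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-16)

    def test_permutation_invariance(self, rng):
        n = 14
        C = _random_cov(rng, n)
        x = rng.uniform(0, 3, n)
        y = 0.5 + 0.7 * x + rng.normal(0, 0.3, n)
        res = gls_fit(x, y, C)
        perm = rng.permutation(n)
        Cp = PhyloCovariance([C.tip_order[i] for i in perm],
                             C.matrix[np.ix_(perm, perm)])
        resp = gls_fit(x[perm], y[perm], Cp)
        assert resp.slope == pytest.approx(res.slope, abs=1e-10)
        assert resp.log_likelihood == pytest.approx(res.log_likelihood, abs=1e-8)


class TestProfileLambda:
    def test_argmax_beats_grid(self, rng):
        tree = simulate_yule_tree(40, rng)
        C = vcv_from_tree(tree)
        y = simulate_bm_lambda(tree, 0.04, 0.7, 0.0, rng).values
        x = rng.uniform(0, 3, 40)
        y = 0.5 + 0.7 * x + y
        lam, (grid, values) = profile_lambda_ml(x, y, C)
        best = gls_fit(x, y, lambda_transform(C, lam)).log_likelihood
        assert best >= values.max() - 1e-9
        assert 0.0 <= lam <= 1.0

    def test_loglik_at_hat_beats_boundaries(self, rng):
        tree = simulate_yule_tree(30, rng)
        C = vcv_from_tree(tree)
        y = 0.3 + 0.7 * rng.uniform(0, 3, 30) + simulate_bm_lambda(
            tree, 0.02, 0.5, 0.0, rng).values
        x = rng.uniform(0, 3, 30)
        lam, _ = profile_lambda_ml(x, y, C)
        ll_hat = gls_fit(x, y, lambda_transform(C, lam)).log_likelihood
        for b in (0.0, 1.0):
            assert ll_hat >= gls_fit(x, y, lambda_transform(C, b)).log_likelihood - 1e-9

    def test_iid_noise_recovers_lambda_zero(self, rng):
        # white residuals carry no phylogenetic signal
        tree = simulate_yule_tree(80, rng)
        C = vcv_from_tree(tree)
        hats = []
        for _ in range(30):
            x = rng.uniform(0, 3, 80)
            y = 0.5 + 0.7 * x + rng.normal(0, 0.1, 80)
            hats.append(profile_lambda_ml(x, y, C)[0])
        assert np.mean(hats) == pytest.approx(0.0, abs=0.05)

    def test_brownian_residuals_recover_lambda_one(self, rng):
        tree = simulate_yule_tree(80, rng)
        C = vcv_from_tree(tree)
        hats = []
        for _ in range(30):
            x = rng.uniform(0, 3, 80)
            y = 0.5 + 0.7 * x + simulate_bm_lambda(tree, 0.04, 1.0, 0.0, rng).values
            hats.append(profile_lambda_ml(x, y, C)[0])
        assert np.mean(hats) == pytest.approx(1.0, abs=0.1)

    def test_needs_four_tips(self):
        with pytest.raises(InsufficientDataError):
            profile_lambda_ml([1, 2, 3], [1, 2, 3],
                              PhyloCovariance(["a", "b", "c"], np.eye(3)))


class TestPGLSAllometry:
    def test_lambda_zero_on_ultrametric_tree_equals_ols(self, rng):
        # with lambda forced to 0 the covariance is a scaled identity on an
        # ultrametric tree, so GLS collapses to OLS
        tree = simulate_yule_tree(20, rng)
        C = lambda_transform(vcv_from_tree(tree), 0.0)
        x = rng.uniform(0, 3, 20)
        y = 0.5 + 0.7 * x + rng.normal(0, 0.1, 20)
        res = gls_fit(x, y, C)
        ols = fit_ols(x, y)
        assert res.slope == pytest.approx(ols.b, abs=1e-10)
        assert res.intercept == pytest.approx(ols.intercept_log10, abs=1e-10)

    def test_too_few_matched_species_refused(self, rng):
        tree = simulate_yule_tree(10, rng)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()][:3]
        recs = make_records("Monotremata", np.array([3.1, 3.5, 4.0]),
                            np.array([2.7, 3.0, 3.3]))
        recs = [SpeciesRecord(t, "Monotremata", r.mass_g, r.bmr)
                for t, r in zip(tips, recs)]
        with pytest.raises(InsufficientDataError):
            pgls_allometry(recs, tree)

    def test_estimates_close_to_truth(self, rng):
        tree = simulate_yule_tree(100, rng)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        x = rng.uniform(0, 4, 100)
        resid = simulate_bm_lambda(tree, 0.01, 0.7, 0.0, rng)
        y = 0.5 + 0.72 * x + resid.values
        recs = [SpeciesRecord(t, "G", 10.0 ** xi, 10.0 ** yi)
                for t, xi, yi in zip(resid.index, x, y)]
        fit = pgls_allometry(recs, tree)
        assert fit.method == "PGLS"
        assert fit.lambda_hat is not None
        assert fit.b == pytest.approx(0.72, abs=3 * fit.se_b)


class TestPruneAndMatch:
    def test_identical_sets_no_drops(self, rng):
        tree = simulate_yule_tree(8, rng)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        recs = [SpeciesRecord(t, "G", 10.0, 5.0) for t in tips]
        aligned, pruned, report = prune_and_match(recs, tree)
        assert report["dropped_records"] == []
        assert report["dropped_tips"] == []
        assert len(aligned) == 8

    def test_extra_tip_pruned_and_reported(self, rng):
        tree = simulate_yule_tree(8, rng)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        recs = [SpeciesRecord(t, "G", 10.0, 5.0) for t in tips[:-1]]
        aligned, pruned, report = prune_and_match(recs, tree)
        assert len(aligned) == 7
        assert report["dropped_tips"] == [tips[-1]]
        assert len([lf for lf in pruned.leaf_node_iter()]) == 7

    def test_matched_count_is_intersection(self, rng):
        tree = simulate_yule_tree(20, rng)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        subset = rng.choice(tips, size=9, replace=False).tolist()
        extra = [SpeciesRecord("not_in_tree", "G", 1.0, 1.0)]
        recs = [SpeciesRecord(t, "G", 10.0, 5.0) for t in subset] + extra
        _, _, report = prune_and_match(recs, tree)
        assert report["n_matched"] == len(set(subset) & set(tips))

    def test_underscore_space_normalization(self, rng):
        tree = tree_from_newick("((Apteryx_australis:1,B_b:1):1,C_c:2);")
        recs = [SpeciesRecord("Apteryx australis", "G", 2000.0, 400.0),
                SpeciesRecord("B b", "G", 10.0, 5.0)]
        aligned, _, report = prune_and_match(recs, tree)
        assert len(aligned) == 2
        assert report["dropped_tips"] == ["C_c"]
        assert normalize_label(" A_b  c ") == "A b c"

    def test_zero_overlap_errors(self, rng):
        tree = simulate_yule_tree(5, rng)
        with pytest.raises(DataValidationError):
            prune_and_match([SpeciesRecord("zz", "G", 1.0, 1.0)], tree)
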