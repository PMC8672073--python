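"""Mixture fitting, model selection, transfer, dependence and stability."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from lightpotential import (
    FeatureSpec,
    fit_gmm,
    fit_linear_effects,
    subsample_robustness,
    transfer_assignments,
    within_cluster_dependence,
)
from lightpotential.cluster import FAMILIES, n_params

COLS = ["resp", "sqrt_par", "t_leaf"]


def make_blobs(n_per, centers, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sd, (n_per, 3)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pd.DataFrame(X, columns=COLS), labels


@pytest.fixture(scope="module")
def two_blob_fit():
    table, labels = make_blobs(200, [0.0, 6.0], seed=1)
    fit = fit_gmm(table, FeatureSpec("resp"), k_range=range(1, 5), n_init=3, seed=0)
    return table, labels, fit


class TestFitGmm:
    def test_selects_k2_with_perfect_ari(self, two_blob_fit):
        _, labels, fit = two_blob_fit
        assert fit.k == 2
        assert adjusted_rand_score(labels, fit.assignments) == 1.0

    def test_em_invariants_on_fit(self, two_blob_fit):
        _, _, fit = two_blob_fit
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-8)
        slack = 1e-10 * max(abs(fit.loglik), 1.0)
        assert (np.diff(fit.loglik_trace) >= -slack).all()
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_selected_bic_is_table_optimum(self, two_blob_fit):
        _, _, fit = two_blob_fit
        ok = fit.bic_table[fit.bic_table["ok"]]
        assert fit.bic == pytest.approx(ok["bic"].min())

    def test_deterministic_given_seed(self):
        table, _ = make_blobs(60, [0.0, 4.0], seed=5)
        spec = FeatureSpec("resp")
        f1 = fit_gmm(table, spec, k_range=range(1, 4), n_init=2, seed=11)
        f2 = fit_gmm(table, spec, k_range=range(1, 4), n_init=2, seed=11)
        assert f1.k == f2.k and f1.family == f2.family
        assert np.array_equal(f1.assignments, f2.assignments)
        assert np.array_equal(f1.means, f2.means)

    def test_single_component_closed_form(self):
        # K=1: responsibilities exactly 1 and BIC equals the Gaussian
        # MLE BIC computed independently
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(0, 1, (80, 3)), columns=COLS)
        reg = 1e-9
        fit = fit_gmm(table, FeatureSpec("resp", standardize=False),
                      k_range=[1], families=["full-varying"], seed=0, reg=reg)
        assert np.all(fit.responsibilities == 1.0)
        X = table.to_numpy()
        cov = np.cov(X.T, bias=True) + reg * np.eye(3)
        loglik = multivariate_normal(X.mean(axis=0), cov).logpdf(X).sum()
        p = n_params("full-varying", 1, 3)
        assert fit.bic == pytest.approx(-2 * loglik + p * np.log(len(X)), rel=1e-8)

    def test_agrees_with_sklearn_reference(self, two_blob_fit):
        # independent implementation check: same family, fixed K
        table, _, _ = two_blob_fit
        mine = fit_gmm(table, FeatureSpec("resp", standardize=False),
                       k_range=[2], families=["full-varying"], n_init=4, seed=0)
        sk = GaussianMixture(2, covariance_type="full", n_init=4,
                             random_state=0, tol=1e-8, max_iter=500,
                             reg_covar=1e-6).fit(table.to_numpy())
        sk_loglik = sk.score(table.to_numpy()) * len(table)
        assert mine.loglik == pytest.approx(sk_loglik, abs=1e-3 * abs(sk_loglik))
        assert adjusted_rand_score(sk.predict(table.to_numpy()), mine.assignments) == 1.0

    def test_label_permutation_invariance(self, two_blob_fit):
        _, labels, fit = two_blob_fit
        relabeled = 1 - fit.assignments
        assert adjusted_rand_score(labels, relabeled) == adjusted_rand_score(
            labels, fit.assignments)

    def test_components_ordered_by_sqrt_par_mean(self):
        table, _ = make_blobs(100, [0.0, 5.0], seed=6)
        fit = fit_gmm(table, FeatureSpec("resp"), k_range=[2],
                      families=["spherical-varying"], seed=0)
        means = fit.means_original
        oi = fit.feature_names.index("sqrt_par")
        assert (np.diff(means[:, oi]) > 0).all()

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame(np.zeros((5, 3)), columns=COLS)
        with pytest.raises(ValueError):
            fit_gmm(table, FeatureSpec("resp"))

    def test_missing_rows_excluded_and_counted(self):
        table, _ = make_blobs(50, [0.0, 4.0], seed=7)
        table.loc[3, "resp"] = np.nan
        fit = fit_gmm(table, FeatureSpec("resp"), k_range=[2],
                      families=["diagonal-varying"], seed=0)
        assert fit.n_dropped == 1
        assert len(fit.assignments) == len(table) - 1


class TestWithinClusterDependence:
    def test_planted_coefficients_recovered(self):
        rng = np.random.default_rng(10)
        n = 200
        sqrt_par = rng.uniform(5, 40, n)
        t_leaf = rng.uniform(15, 35, n)
        resp = 3.0 * sqrt_par + rng.normal(0, 1.0, n)  # zero t_leaf effect
        table = pd.DataFrame({"resp": resp, "sqrt_par": sqrt_par, "t_leaf": t_leaf})
        dep = within_cluster_dependence(table, np.zeros(n, dtype=int), "resp")
        row_par = dep[dep["term"] == "sqrt_par"].iloc[0]
        row_t = dep[dep["term"] == "t_leaf"].iloc[0]
        assert row_par["coef"] == pytest.approx(3.0, abs=3 * row_par["se"])
        assert row_par["significant"]
        assert not row_t["significant"]

    def test_constant_response_flagged_zero_variance(self):
        table = pd.DataFrame({"resp": np.ones(30),
                              "sqrt_par": np.arange(30.0),
                              "t_leaf": np.arange(30.0) % 7})
        dep = within_cluster_dependence(table, np.zeros(30, dtype=int), "resp")
        assert (dep["note"] == "zero-variance response").all()
        assert (dep.loc[dep["term"] == "sqrt_par", "coef"] == 0).all()

    def test_collinear_covariates_inestimable(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        table = pd.DataFrame({"resp": rng.normal(0, 1, 40),
                              "sqrt_par": x, "t_leaf": 2 * x})
        dep = within_cluster_dependence(table, np.zeros(40, dtype=int), "resp")
        assert dep["note"].str.contains("inestimable").all()

    def test_small_cluster_untestable(self):
        table = pd.DataFrame({"resp": [1.0, 2.0], "sqrt_par": [1.0, 2.0],
                              "t_leaf": [3.0, 4.0]})
        dep = within_cluster_dependence(table, np.zeros(2, dtype=int), "resp")
        assert dep.iloc[0]["note"].startswith("untestable")


class TestLinearEffects:
    def test_additive_model_interaction_rarely_significant(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            n = 500
            a = rng.uniform(0, 10, n)
            b = rng.uniform(0, 10, n)
            y = 2.0 * a + 1.0 * b + rng.normal(0, 1, n)
            table = pd.DataFrame({"y": y, "sqrt_par": a, "t_leaf": b})
            fit = fit_linear_effects(table, "y")
            hits += fit.pvalues["sqrt_par:t_leaf"] >= 0.05
        assert hits >= 90

    def test_planted_interaction_recovered(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            n = 500
            a = rng.uniform(0, 10, n)
            b = rng.uniform(0, 10, n)
            y = 2.0 * a + 1.0 * b + 0.5 * a * b + rng.normal(0, 1, n)
            table = pd.DataFrame({"y": y, "sqrt_par": a, "t_leaf": b})
            fit = fit_linear_effects(table, "y")
            est = fit.params["sqrt_par:t_leaf"]
            se = fit.bse["sqrt_par:t_leaf"]
            hits += abs(est - 0.5) <= 2 * se
        assert hits >= 90

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_effects(pd.DataFrame(columns=["y", "sqrt_par", "t_leaf"]), "y")


class TestTransfer:
    def test_identity_transfer_matches_baseline(self, two_blob_fit):
        table, _, fit = two_blob_fit
        res = transfer_assignments(fit, table, "resp")
        for c in range(fit.k):
            in_c = fit.assignments == c
            assert res.summaries.loc[res.summaries["cluster"] == c, "mean"].iloc[0] == (
                pytest.approx(table.loc[fit.row_index][in_c]["resp"].mean()))

    def test_row_mismatch_rejected(self, two_blob_fit):
        table, _, fit = two_blob_fit
        with pytest.raises(ValueError):
            transfer_assignments(fit, table.iloc[:50], "resp")

    def test_permuted_response_destroys_dependence(self):
        rng = np.random.default_rng(20)
        n = 300
        sqrt_par = rng.uniform(5, 40, n)
        t_leaf = rng.uniform(15, 35, n)
        resp = 2.0 * sqrt_par + 1.5 * t_leaf + rng.normal(0, 2, n)
        table = pd.DataFrame({"resp": resp, "sqrt_par": sqrt_par, "t_leaf": t_leaf,
                              "perm": rng.permutation(resp)})
        labels = np.zeros(n, dtype=int)
        dep = within_cluster_dependence(table, labels, "resp")
        dep_perm = within_cluster_dependence(table, labels, "perm")
        t_real = dep.loc[dep["term"] != "const", "t"].abs().median()
        t_perm = dep_perm.loc[dep_perm["term"] != "const", "t"].abs().median()
        assert t_perm < t_real / 3

    def test_simulator_npq_high_strengthens_t_leaf_dependence(self, default_table):
        # the rapid NPQ response carries regime structure driven by T_leaf,
        # so transferring the ambient-NPQ clustering onto NPQ_high must
        # sharpen the within-cluster T_leaf dependence
        table, _ = default_table
        clean = table[table["notes"] == ""].reset_index(drop=True)
        fit = fit_gmm(clean, FeatureSpec("npqt_amb"), k_range=range(1, 4),
                      families=["full-varying"], n_init=2, seed=0)
        base = transfer_assignments(fit, clean, "npqt_amb")
        high = transfer_assignments(fit, clean, "npqt_high")
        t_base = base.dependence.query("term == 't_leaf'")["t"].abs().mean()
        t_high = high.dependence.query("term == 't_leaf'")["t"].abs().mean()
        assert t_high > t_base


class TestSubsampleRobustness:
    def test_full_fraction_is_identity(self):
        table, _ = make_blobs(80, [0.0, 6.0], seed=3)
        rep = subsample_robustness(table, FeatureSpec("resp"), fractions=[1.0],
                                   n_reps=2, seed=0, k_range=range(1, 4), n_init=2)
        assert (rep["ari"] == 1.0).all()
        assert rep["selected_k"].nunique() == 1

    def test_tiny_subsample_skipped(self):
        table, _ = make_blobs(50, [0.0, 6.0], seed=3)
        rep = subsample_robustness(table, FeatureSpec("resp"), fractions=[0.05],
                                   n_reps=1, seed=0, k_range=range(1, 3), n_init=2)
        assert rep.iloc[0]["note"].startswith("skipped")

    def test_invalid_fraction_rejected(self):
        table, _ = make_blobs(50, [0.0, 6.0], seed=3)
        with pytest.raises(ValueError):
            subsample_robustness(table, FeatureSpec("resp"), fractions=[1.5])
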