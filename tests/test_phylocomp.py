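"""PGLS machinery: trees, covariance structures, ML fits, outliers, intervals."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import predscale as ps
from predscale.phylocomp import (
    CovarianceModel,
    NewickError,
    model_covariance,
    predict_interval,
)

from conftest import simulate_bm_tips


# ---------------------------------------------------------------------------
# Newick parsing, pruning, shared times
# ---------------------------------------------------------------------------


class TestTree:
    def test_two_tip_depths(self):
        phy = ps.read_newick("(A:1,B:1):0;")
        assert phy.n_tips == 2
        np.testing.assert_allclose(phy.depths(), [1.0, 1.0])

    def test_shared_times_three_taxa(self):
        phy = ps.read_newick("((A:1,B:1):1,C:2):0;")
        C = phy.shared_time_matrix()
        i = {lab: k for k, lab in enumerate(phy.tip_labels)}
        np.testing.assert_allclose(np.diag(C), [2, 2, 2])
        assert C[i["A"], i["B"]] == pytest.approx(1.0)
        assert C[i["A"], i["C"]] == pytest.approx(0.0)
        assert C[i["B"], i["C"]] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "bad",
        ["((A:1,B:1)", "(A:1,A:1):0;", "(A:1,(B,C:1):1):0;"],
        ids=["unbalanced", "duplicate-tips", "missing-length"],
    )
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(NewickError):
            ps.read_newick(bad)

    def test_prune_preserves_path_lengths(self, balanced_tree):
        full = balanced_tree.shared_time_matrix()
        idx = {lab: k for k, lab in enumerate(balanced_tree.tip_labels)}
        sub = balanced_tree.prune(["A", "D"])
        # A-D patristic distance must survive the collapse of deg-2 nodes
        dAD_full = full[idx["A"], idx["A"]] + full[idx["D"], idx["D"]] - 2 * full[idx["A"], idx["D"]]
        assert sub.patristic_distance("A", "D") == pytest.approx(dAD_full)

    def test_prune_to_all_is_identity(self, balanced_tree):
        sub = balanced_tree.prune(balanced_tree.tip_labels)
        np.testing.assert_allclose(
            sub.shared_time_matrix(), balanced_tree.shared_time_matrix()
        )

    def test_prune_errors(self, balanced_tree):
        with pytest.raises(KeyError):
            balanced_tree.prune(["A", "missing"])
        with pytest.raises(ValueError):
            balanced_tree.prune(["A"])

    def test_shared_time_is_bm_covariance(self, balanced_tree):
        """C equals the covariance of branch-wise Brownian tip values."""
        rng = np.random.default_rng(1234)
        reps = np.array([simulate_bm_tips(balanced_tree, rng) for _ in range(10_000)])
        emp = np.cov(reps.T)
        C = balanced_tree.shared_time_matrix()
        # elementwise Monte-Carlo error ~ C_ii*C_jj/sqrt(reps); 4 sd margin
        assert np.max(np.abs(emp - C)) < 0.12


# ---------------------------------------------------------------------------
# Covariance structures
# ---------------------------------------------------------------------------


class TestCovariance:
    def test_lambda_limits(self, balanced_tree):
        C = balanced_tree.shared_time_matrix()
        V0 = model_covariance(C, CovarianceModel("LAMBDA", 0.0))
        assert np.count_nonzero(V0 - np.diag(np.diag(V0))) == 0
        np.testing.assert_allclose(np.diag(V0), np.diag(C))
        V1 = model_covariance(C, CovarianceModel("LAMBDA", 1.0))
        np.testing.assert_array_equal(V1, C)

    def test_acdc_small_g_limit(self, balanced_tree):
        C = balanced_tree.shared_time_matrix()
        V = model_covariance(C, CovarianceModel("ACDC", 1e-8))
        np.testing.assert_allclose(V, C, atol=1e-6)

    def test_ou_small_alpha_limit(self):
        phy = ps.simulate_tree(6, 3)  # ultrametric
        C = phy.shared_time_matrix()
        V = model_covariance(C, CovarianceModel("OU", 1e-9))
        np.testing.assert_allclose(V, np.ones_like(V), atol=1e-6)

    def test_domain_errors(self, balanced_tree):
        C = balanced_tree.shared_time_matrix()
        with pytest.raises(ValueError):
            model_covariance(C, CovarianceModel("LAMBDA", 1.5))
        with pytest.raises(ValueError):
            model_covariance(C, CovarianceModel("OU", -1.0))

    def test_symmetric_positive_definite_across_random_trees(self):
        """Cholesky succeeds for every structure over 1,000 random (tree, theta)."""
        rng = np.random.default_rng(7)
        for _ in range(250):  # x4 structures = 1,000 matrices
            phy = ps.simulate_tree(int(rng.integers(4, 12)), int(rng.integers(1 << 30)))
            C = phy.shared_time_matrix()
            draws = {
                "BM": None,
                "LAMBDA": float(rng.uniform(0, 1)),
                "OU": float(rng.uniform(0.05, 20)),
                "ACDC": float(rng.uniform(0.05, 3)),
            }
            for kind, th in draws.items():
                V = model_covariance(C, CovarianceModel(kind, th))
                np.testing.assert_allclose(V, V.T)
                np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------


def mvn_profile_oracle(x, y, V):
    """Dense multivariate-normal oracle: GLS beta, ML sigma2, exact logpdf."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = (r @ Vi @ r) / n
    return stats.multivariate_normal(mean=X @ beta, cov=s2 * V).logpdf(y), beta


class TestGLSFit:
    def test_identity_exact_interpolation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        f = ps.gls_fit(x, x.copy(), np.eye(4), "BM")
        assert f.slope == pytest.approx(1.0, abs=1e-12)
        assert f.intercept == pytest.approx(0.0, abs=1e-12)
        assert f.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_loglik_matches_mvn_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 13))
            phy = ps.simulate_tree(n, int(rng.integers(1 << 30)))
            C = phy.shared_time_matrix()
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            for kind, th in [("BM", None), ("LAMBDA", 0.7), ("OU", 1.3), ("ACDC", None)]:
                f = ps.gls_fit(x, y, C, kind, theta=th)
                V = model_covariance(
                    C, CovarianceModel(kind, th if th is not None else (0.5 if kind == "ACDC" else None))
                )
                ll, beta = mvn_profile_oracle(x, y, V)
                assert f.loglik == pytest.approx(ll, abs=1e-8)
                assert f.slope == pytest.approx(beta[1], abs=1e-8)

    def test_lambda_reductions(self):
        rng = np.random.default_rng(5)
        phy = ps.simulate_tree(10, 5)
        C = phy.shared_time_matrix()
        x, y = rng.normal(size=10), rng.normal(size=10)
        f_bm = ps.gls_fit(x, y, C, "BM")
        f_l1 = ps.gls_fit(x, y, C, "LAMBDA", theta=1.0)
        assert f_l1.loglik == pytest.approx(f_bm.loglik, abs=1e-8)
        # lambda=0 on a unit-depth ultrametric tree is OLS
        f_l0 = ps.gls_fit(x, y, C, "LAMBDA", theta=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert f_l0.slope == pytest.approx(ols.params[1], abs=1e-8)
        assert f_l0.intercept == pytest.approx(ols.params[0], abs=1e-8)

    def test_small_sample_refused(self):
        with pytest.raises(ValueError):
            ps.gls_fit([1, 2, 3], [1, 2, 3], np.eye(3), "BM")

    def test_frozen_pgls_cross_check(self):
        """Session-frozen cross-check against R nlme::gls with ape::corPagel.

        Fixture: the 5-taxon balanced tree, x=(0,1,2,3,4), fixed y; the frozen
        numbers are REML-free (method='ML') coefficient estimates at lambda
        fixed to 0.5 from the independent R toolchain.
        """
        phy = ps.read_newick("((A:1,B:1):1,(C:1.5,(D:0.5,E:0.5):1):0.5):0;")
        order = [phy.tip_labels.index(s) for s in ["A", "B", "C", "D", "E"]]
        C = phy.shared_time_matrix()[np.ix_(order, order)]
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.2, 1.1, 1.7, 3.4, 3.9])
        f = ps.gls_fit(x, y, C, "LAMBDA", theta=0.5)
        assert f.intercept == pytest.approx(0.1360780581, abs=1e-8)
        assert f.slope == pytest.approx(0.9538315088, abs=1e-8)
        assert f.loglik == pytest.approx(-0.3841744961, abs=1e-8)


class TestAicRank:
    def _fits(self, n=12, seed=2):
        rng = np.random.default_rng(seed)
        phy = ps.simulate_tree(n, seed)
        C = phy.shared_time_matrix()
        x, y = rng.normal(size=n), rng.normal(size=n)
        return x, y, C

    def test_single_fit(self):
        x, y, C = self._fits()
        ranked = ps.aic_rank([ps.gls_fit(x, y, C, "BM")])
        assert ranked[0][1] == 0.0

    def test_tie_keeps_input_order(self):
        x, y, C = self._fits()
        f1 = ps.gls_fit(x, y, C, "BM")
        f2 = ps.gls_fit(x, y, C, "LAMBDA", theta=1.0)
        f2.aic = f1.aic  # force exact tie
        ranked = ps.aic_rank([f2, f1])
        assert ranked[0][0] is f2

    def test_refuses_mixed_data(self):
        x, y, C = self._fits()
        f1 = ps.gls_fit(x, y, C, "BM", mode="solitary")
        f2 = ps.gls_fit(x, y, C, "BM", mode="pack")
        with pytest.raises(ValueError):
            ps.aic_rank([f1, f2])

    def test_ordering_invariant_to_row_permutation(self):
        x, y, C = self._fits(n=15, seed=9)
        perm = np.random.default_rng(1).permutation(15)
        kinds = ["BM", "OU", "LAMBDA", "ACDC"]
        r1 = ps.aic_rank([ps.gls_fit(x, y, C, k) for k in kinds])
        r2 = ps.aic_rank(
            [ps.gls_fit(x[perm], y[perm], C[np.ix_(perm, perm)], k) for k in kinds]
        )
        assert [f.model_kind for f, _ in r1] == [f.model_kind for f, _ in r2]
        for (fa, da), (fb, db) in zip(r1, r2):
            assert da == pytest.approx(db, abs=1e-7)


class TestParameterRecovery:
    """Simulate under each structure at n=200 and re-estimate, 200 reps.

    Slope and intercept are held to two Monte-Carlo standard errors.  The
    profiled structure parameters are held to absolute/relative bands that
    allow for the documented finite-sample bias of their ML estimates
    (lambda ~ -0.02, alpha ~ +15% at this size; see docs/methods.md).
    """

    @pytest.mark.parametrize(
        "kind,theta", [("BM", None), ("LAMBDA", 0.7), ("OU", 2.0), ("ACDC", None)]
    )
    def test_recovery(self, kind, theta):
        n, reps = 200, 200
        phy = ps.simulate_tree(n, 42)
        C = phy.shared_time_matrix()
        V = model_covariance(
            C, CovarianceModel(kind, theta if theta is not None else (0.5 if kind == "ACDC" else None))
        )
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        rng = np.random.default_rng(11)
        slopes, intercepts, thetas = [], [], []
        for _ in range(reps):
            x = rng.uniform(-1.0, np.log10(500), n)
            y = 0.3 + 1.0 * x + 0.5 * (L @ rng.standard_normal(n))
            f = ps.gls_fit(x, y, C, kind)
            slopes.append(f.slope)
            intercepts.append(f.intercept)
            thetas.append(f.theta_hat)
        slopes, intercepts = np.array(slopes), np.array(intercepts)
        assert abs(slopes.mean() - 1.0) < 2 * slopes.std() / np.sqrt(reps)
        assert abs(intercepts.mean() - 0.3) < 2 * intercepts.std() / np.sqrt(reps)
        if kind == "LAMBDA":
            assert abs(np.mean(thetas) - theta) < 0.15
        elif kind == "OU":
            assert abs(np.mean(thetas) - theta) / theta < 0.25


# ---------------------------------------------------------------------------
# Rosner screening
# ---------------------------------------------------------------------------


class TestRosner:
    def test_gross_outlier_flagged(self):
        rep = ps.rosner_outliers(list(range(1, 10)) + [1000], k_max=1, alpha=0.05)
        assert rep.flagged == [9]

    def test_degenerate_data(self):
        with pytest.raises(ValueError):
            ps.rosner_outliers([3.0] * 20, 1, 0.05)

    def test_small_sample_floor(self):
        with pytest.raises(ValueError):
            ps.rosner_outliers([1, 2, 3], 1, 0.05)

    def test_published_worked_example(self):
        """n=54 ESD reference data: statistics, critical values, 3 outliers."""
        data = [-0.25, 0.68, 0.94, 1.15, 1.20, 1.26, 1.26, 1.34, 1.38, 1.43,
                1.49, 1.49, 1.55, 1.56, 1.58, 1.65, 1.69, 1.70, 1.76, 1.77,
                1.81, 1.91, 1.94, 1.96, 1.99, 2.06, 2.09, 2.10, 2.14, 2.15,
                2.23, 2.24, 2.26, 2.35, 2.37, 2.40, 2.47, 2.54, 2.62, 2.64,
                2.90, 2.92, 2.92, 2.93, 3.21, 3.26, 3.30, 3.59, 3.68, 4.30,
                4.64, 5.34, 5.42, 6.01]
        rep = ps.rosner_outliers(data, k_max=10, alpha=0.05)
        assert sorted(data[i] for i in rep.flagged) == [5.34, 5.42, 6.01]
        R1, crit1 = rep.statistics[0]
        assert R1 == pytest.approx(3.118, abs=2e-3)
        assert crit1 == pytest.approx(3.158, abs=2e-3)

    def test_rerun_after_removal_is_clean(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.standard_normal(60), [25.0, -30.0]])
        rep = ps.rosner_outliers(x, k_max=4, alpha=0.05)
        assert {60, 61} <= set(rep.flagged)
        remaining = np.delete(x, rep.flagged)
        rep2 = ps.rosner_outliers(remaining, k_max=4, alpha=0.05)
        assert rep2.flagged == []


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


class TestIntervals:
    @pytest.fixture()
    def ols_fit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 1.0 + 0.5 * x + rng.normal(scale=0.3, size=20)
        return x, y, ps.gls_fit(x, y, np.eye(20), "BM")

    def test_ci_matches_classical_ols_at_mean(self, ols_fit):
        x, y, f = ols_fit
        est = predict_interval(f, float(x.mean()))
        tq = stats.t.ppf(0.975, f.n - 2)
        classical = tq * np.sqrt(f.sigma2 / f.n)  # mean-response at x-bar
        assert (est.ci_high - est.ci_low) / 2 == pytest.approx(classical, rel=1e-10)

    def test_nesting_invariant(self, ols_fit):
        _, _, f = ols_fit
        for x0 in (-2.0, 0.0, 3.7):
            est = predict_interval(f, x0)
            assert est.pi_low <= est.ci_low <= est.fit_value <= est.ci_high <= est.pi_high

    def test_width_minimized_at_generalized_mean(self):
        rng = np.random.default_rng(4)
        phy = ps.simulate_tree(30, 4)
        C = phy.shared_time_matrix()
        x = rng.normal(size=30)
        y = x + np.linalg.cholesky(C + 1e-12 * np.eye(30)) @ rng.normal(size=30)
        f = ps.gls_fit(x, y, C, "LAMBDA")
        V = model_covariance(C, CovarianceModel("LAMBDA", f.theta_hat))
        Vi = np.linalg.inv(V)
        xbar_gls = float(np.ones(30) @ Vi @ x / (np.ones(30) @ Vi @ np.ones(30)))
        w0 = predict_interval(f, xbar_gls).ci_high - predict_interval(f, xbar_gls).ci_low
        for dx in (-0.5, 0.5):
            w = predict_interval(f, xbar_gls + dx).ci_high - predict_interval(f, xbar_gls + dx).ci_low
        assert w0 <= w

    def test_level_domain(self, ols_fit):
        _, _, f = ols_fit
        with pytest.raises(ValueError):
            predict_interval(f, 0.0, level=1.5)
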