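import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pavbias.longitudinal import (cluster_fit_values, fit_lcs, gaussianize,
                                  retest_statistics)


def _tables(x, y, name="b_pav"):
    ids = [f"P{i}" for i in range(len(x))]
    return (pd.DataFrame({name: x}, index=ids),
            pd.DataFrame({name: y}, index=ids))


class TestRetestStatistics:
    def test_identical_tables(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        t1, t2 = _tables(x, x)
        res = retest_statistics(t1, t2)
        assert res.loc["b_pav", "r"] == pytest.approx(1.0)
        assert res.loc["b_pav", "change_p"] == 1.0

    def test_independent_columns_near_null(self):
        rng = np.random.default_rng(1)
        t1, t2 = _tables(rng.normal(0, 1, 500), rng.normal(0, 1, 500),
                         name="il")
        res = retest_statistics(t1, t2)
        assert abs(res.loc["il", "r"]) < 0.09      # 95% null band at n=500
        assert res.loc["il", "method"] == "pearson"

    def test_method_selection_and_bonferroni(self):
        rng = np.random.default_rng(2)
        ids = [f"P{i}" for i in range(40)]
        t1 = pd.DataFrame({"b_pav": rng.lognormal(size=40),
                           "b_go": rng.normal(size=40)}, index=ids)
        t2 = t1 + rng.normal(0, 0.1, size=(40, 2))
        res = retest_statistics(t1, t2)
        assert res.loc["b_pav", "method"] == "spearman"
        assert res.loc["b_go", "method"] == "pearson"
        assert (res["change_p_bonferroni"] >= res["change_p"] - 1e-12).all()

    def test_requires_overlap(self):
        t1 = pd.DataFrame({"a": np.arange(12.)},
                          index=[f"A{i}" for i in range(12)])
        t2 = pd.DataFrame({"a": np.arange(12.)},
                          index=[f"B{i}" for i in range(12)])
        with pytest.raises(ValueError):
            retest_statistics(t1, t2)


class TestGaussianize:
    def test_preserves_ranks_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1.5, 400)
        z = gaussianize(x)
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)

    def test_matches_input_moments(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(3.0, 250)
        z = gaussianize(x)
        assert z.mean() == pytest.approx(x.mean(), rel=1e-9)
        assert z.std() == pytest.approx(x.std(), rel=1e-9)

    def test_near_identity_on_gaussian_input(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(5000)
        z = gaussianize(x)
        assert np.mean(np.abs(z - x)) < 0.05

    def test_normalizes_heavy_skew(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 1.0, 1000)
        assert stats.normaltest(x).pvalue < 1e-10
        assert stats.normaltest(gaussianize(x)).pvalue > 0.01

    def test_idempotent_up_to_tolerance(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 1.0, 500)
        once = gaussianize(x)
        twice = gaussianize(once)
        assert np.max(np.abs(twice - once)) < 1e-8

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            gaussianize(np.ones(50))
        with pytest.raises(ValueError):
            gaussianize(np.arange(5.0))


class TestLatentChangeScore:
    def test_no_change_data(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 200)
        res = fit_lcs(x, x)
        assert res.beta == pytest.approx(0.0, abs=1e-10)
        assert res.change_mean == pytest.approx(0.0, abs=1e-12)
        assert res.change_var == pytest.approx(0.0, abs=1e-10)

    def test_independence_gives_pure_regression_to_mean(self):
        rng = np.random.default_rng(9)
        x1 = rng.normal(0, 1, 2000)
        x2 = rng.normal(0, 1, 2000)
        res = fit_lcs(x1, x2)
        assert res.beta == pytest.approx(-1.0, abs=0.1)
        # the beta = -1 model should NOT be rejected
        assert res.p_rtm > 0.05

    def test_planted_self_feedback_recovered(self):
        rng = np.random.default_rng(10)
        n, beta = 2000, -0.5
        x1 = rng.normal(0.3, 1.2, n)
        delta = 0.1 + beta * x1 + rng.normal(0, 0.8, n)
        res = fit_lcs(x1, x1 + delta)
        assert res.beta == pytest.approx(beta, abs=0.1)
        assert res.p_rtm < 1e-6          # LRT rejects pure regression to mean
        assert res.alpha == pytest.approx(0.1, abs=0.15)

    def test_just_identified_model_reproduces_sample_moments(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(0, 1, 300)
        x2 = 0.4 * x1 + rng.normal(0, 0.9, 300) + 0.2
        res = fit_lcs(x1, x2)
        assert res.implied_mean[0] == pytest.approx(x1.mean())
        assert res.implied_mean[1] == pytest.approx(x2.mean())
        assert res.implied_cov[0, 0] == pytest.approx(x1.var())
        assert res.implied_cov[0, 1] == pytest.approx(
            np.mean((x1 - x1.mean()) * (x2 - x2.mean())))
        # nested models never beat the saturated likelihood
        assert res.chi2_rtm >= 0 and res.chi2_nochange >= 0

    def test_no_change_population_accepts_equality_model(self):
        rng = np.random.default_rng(12)
        x1 = rng.normal(0, 1, 1500)
        x2 = 0.5 * x1 + rng.normal(0, np.sqrt(0.75), 1500)
        res = fit_lcs(x1, x2)
        assert res.p_nochange > 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_lcs(np.arange(10.0), np.arange(10.0))
        x = np.arange(40.0)
        y = x.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_lcs(x, y)


class TestClusterFitValues:
    def test_single_component_selected_for_one_gaussian(self):
        rng = np.random.default_rng(13)
        x = rng.multivariate_normal([-70, -65], [[20, 8], [8, 15]], 1000)
        model = cluster_fit_values(x[:, 0], x[:, 1], n_init=5, seed=0)
        assert model.k == 1

    def test_planted_two_components_recovered(self):
        rng = np.random.default_rng(14)
        a = rng.multivariate_normal([-80, -80], np.eye(2), 250)
        b = rng.multivariate_normal([-75, -75], np.eye(2), 250)
        x = np.vstack([a, b])
        model = cluster_fit_values(x[:, 0], x[:, 1], n_init=5, seed=0)
        assert model.k == 2
        got = model.means[np.argsort(model.means[:, 0])]
        assert np.allclose(got, [[-80, -80], [-75, -75]], atol=0.5)
        assert model.sizes.sum() == 500
        assert abs(model.sizes[0] - 250) < 40

    def test_bic_table_covers_candidates(self):
        rng = np.random.default_rng(15)
        x = rng.normal(-70, 3, 120)
        y = x + rng.normal(0, 2, 120)
        model = cluster_fit_values(x, y, k_candidates=range(1, 4), n_init=3,
                                   seed=0)
        assert set(model.bic_by_k) == {1, 2, 3}
        assert model.weights.sum() == pytest.approx(1.0)
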