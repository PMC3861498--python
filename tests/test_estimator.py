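"""Estimator: sample logistic fit, intercept correction and delta method."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import casebase as cb


def test_saturated_fit_closed_form(hand_dataset):
    """A saturated single-binary-exposure fit has exp(alpha*) = a0/b0 and
    exp(alpha* + beta) = a1/b1; the corrected intercept multiplies by
    rho_hat = 0.2 and the reference risk follows in closed form."""
    fit = cb.fit_casebase(hand_dataset, ["x"])
    assert np.exp(fit.alpha_star) == pytest.approx(4 / 21, rel=1e-12)
    assert np.exp(fit.alpha_star + fit.beta_hat[0]) == pytest.approx(
        6 / 9, rel=1e-12)
    assert fit.rho.rho_hat == pytest.approx(0.2, abs=1e-15)
    assert np.exp(fit.alpha_hat) == pytest.approx(4 / 21 * 0.2, rel=1e-12)
    risk0 = cb.estimate_risk(fit, {"x": 0})
    q = 4 / 21 * 0.2
    assert risk0.point == pytest.approx(q / (1 + q), rel=1e-10)
    assert risk0.point == pytest.approx(0.0367, abs=5e-5)


def test_rho_gamma_binomial_formulas():
    est = cb.estimate_rho_gamma(cb.SamplingCounts(n_D=500, n1=50, n11=5))
    assert est.rho_hat == pytest.approx(0.1)
    assert est.var_rho == pytest.approx(0.1 * 0.9 / 500, rel=1e-12)
    assert est.var_log_rho == pytest.approx(0.018, rel=1e-12)
    assert est.gamma_hat == pytest.approx(0.1)
    assert est.var_gamma == pytest.approx(0.1 * 0.9 / 50, rel=1e-12)


def test_rho_one_reduces_to_cohort_analysis(scenario1_dataset):
    """A census of the diseased (everyone in the base sample) makes rho = 1
    exactly and every output equal to a plain cohort logistic analysis."""
    ds = scenario1_dataset.copy()
    ds["in_base_sample"] = 1
    fit = cb.fit_casebase(ds, ["x"])
    assert fit.rho.rho_hat == 1.0
    assert fit.rho.var_log_rho == 0.0
    assert fit.alpha_hat == fit.alpha_star
    X = sm.add_constant(ds[["x"]].to_numpy())
    ref = sm.GLM(ds["disease"].to_numpy(), X,
                 family=sm.families.Binomial()).fit(tol=1e-13, maxiter=200)
    assert fit.alpha_hat == pytest.approx(ref.params[0], abs=1e-10)
    assert fit.beta_hat[0] == pytest.approx(ref.params[1], abs=1e-10)
    assert np.allclose(fit.logistic.covariance, ref.cov_params(), atol=1e-10)
    # risk at x=1 equals the cohort fitted probability, with matching se
    r = cb.estimate_risk(fit, {"x": 1})
    assert r.point == pytest.approx(expit(ref.params.sum()), abs=1e-10)


def test_census_risk_equals_group_proportion(scenario1_model):
    """On census data a saturated fit returns empirical group fractions."""
    pop = cb.simulate_population(scenario1_model, 3000, seed=21)
    ds = cb.draw_case_base_sample(pop, cb.SamplingDesign(3000, 0.0, 1.0),
                                  seed=22)
    fit = cb.fit_casebase(ds, ["x"])
    grp = ds.groupby("x")["disease"].mean()
    assert cb.estimate_risk(fit, {"x": 0}).point == pytest.approx(
        grp[0.0], rel=1e-10)
    assert cb.estimate_risk(fit, {"x": 1}).point == pytest.approx(
        grp[1.0], rel=1e-10)


def test_rr_equals_ratio_of_risks(scenario1_dataset):
    fit = cb.fit_casebase(scenario1_dataset, ["x"])
    rr = cb.estimate_rr(fit, {"x": 1}, {"x": 0})
    r1 = cb.estimate_risk(fit, {"x": 1})
    r0 = cb.estimate_risk(fit, {"x": 0})
    assert rr.point == pytest.approx(r1.point / r0.point, rel=1e-14)


def test_identical_profiles_give_unit_rr(scenario1_dataset):
    fit = cb.fit_casebase(scenario1_dataset, ["x"])
    rr = cb.estimate_rr(fit, {"x": 1}, {"x": 1})
    assert rr.point == 1.0 and rr.se_transformed == 0.0
    assert rr.ci_low == rr.ci_high == 1.0


def test_or_contrasts(scenario1_dataset):
    fit = cb.fit_casebase(scenario1_dataset, ["x"])
    by_name = cb.estimate_or(fit, "x")
    by_vec = cb.estimate_or(fit, [1.0])
    assert by_name.transformed_point == by_vec.transformed_point
    null = cb.estimate_or(fit, [0.0])
    assert null.point == 1.0 and null.se_transformed == 0.0


def test_delta_variance_matches_numerical_gradient(scenario1_dataset):
    """The closed-form gradient of log RR w.r.t. (alpha*, beta, log rho)
    agrees with central finite differences."""
    fit = cb.fit_casebase(scenario1_dataset, ["x"])
    p0 = np.concatenate([[fit.alpha_star], fit.beta_hat,
                         [np.log(fit.rho.rho_hat)]])

    def log_rr(params):
        a, b, lr = params[0], params[1:-1], params[-1]
        l1 = a + lr + b[0]
        l0 = a + lr
        return np.log(expit(l1)) - np.log(expit(l0))

    h = 1e-6
    g = np.array([
        (log_rr(p0 + h * e) - log_rr(p0 - h * e)) / (2 * h)
        for e in np.eye(p0.size)])
    cov = np.zeros((3, 3))
    cov[:2, :2] = fit.logistic.covariance
    cov[2, 2] = fit.rho.var_log_rho
    var_num = g @ cov @ g
    var_ana = cb.estimate_rr(fit, {"x": 1}, {"x": 0}).se_transformed ** 2
    assert var_ana == pytest.approx(var_num, rel=1e-6)


def test_n1_zero_keeps_ors_refuses_risks(hand_dataset):
    ds = hand_dataset[~((hand_dataset["disease"] == 1)
                        & (hand_dataset["in_base_sample"] == 1))].copy()
    fit = cb.fit_casebase(ds, ["x"])
    assert not fit.rho.estimable
    assert np.isnan(fit.alpha_hat)
    assert np.isfinite(cb.estimate_or(fit, "x").point)
    with pytest.raises(cb.NotEstimableError):
        cb.estimate_risk(fit, {"x": 0})
    with pytest.raises(cb.NotEstimableError):
        cb.estimate_rr(fit, {"x": 1}, {"x": 0})


def test_n11_zero_is_harmless(hand_dataset):
    """Emptying the case/base overlap leaves gamma unavailable but changes
    no risk output (n1 and n_D are preserved)."""
    fit_ref = cb.fit_casebase(hand_dataset, ["x"])
    ds = hand_dataset.copy()
    # move the diseased base members out of the case sample (they stay
    # recruited through the base sample), so n11 = 0 with n1, n_D unchanged
    sel = (ds["disease"] == 1) & (ds["in_base_sample"] == 1)
    ds.loc[sel, "in_case_sample"] = 0
    fit = cb.fit_casebase(ds, ["x"])
    assert fit.rho.n11 == 0
    assert np.isnan(fit.rho.gamma_hat)
    r_ref = cb.estimate_risk(fit_ref, {"x": 1})
    r = cb.estimate_risk(fit, {"x": 1})
    assert r.point == r_ref.point
    assert r.se_transformed == r_ref.se_transformed


def test_all_diseased_raises_separation_error(hand_dataset):
    ds = hand_dataset[hand_dataset["disease"] == 1]
    with pytest.raises(cb.SeparationError):
        cb.fit_casebase(ds, ["x"])


def test_perfect_separation_names_problem(hand_dataset):
    ds = hand_dataset.copy()
    ds["z"] = ds["disease"]  # perfectly predictive covariate
    with pytest.raises(cb.SeparationError):
        cb.fit_casebase(ds, ["x", "z"])


def test_rank_deficiency_detected(hand_dataset):
    ds = hand_dataset.copy()
    ds["x2"] = ds["x"]
    with pytest.raises(cb.RankDeficientError):
        cb.fit_casebase(ds, ["x", "x2"])


def test_covariance_is_symmetric_psd(scenario1_dataset):
    fit = cb.fit_casebase(scenario1_dataset, ["x"])
    V = fit.logistic.covariance
    assert np.allclose(V, V.T, atol=1e-10)
    assert (np.linalg.eigvalsh(V) > 0).all()


def test_dummy_and_interaction_terms(scenario1_dataset):
    """C() expands to reference-coded indicators and a:b to a product
    column; profile dicts re-use the fitted encoding."""
    ds = scenario1_dataset.copy()
    rng = np.random.default_rng(0)
    ds["g"] = rng.integers(0, 3, len(ds)).astype(float)
    fit = cb.fit_casebase(ds, ["x", "C(g)", "x:g"])
    assert fit.columns == ["x", "g[1]", "g[2]", "x:g"]
    r = cb.estimate_risk(fit, {"x": 1, "g": 2})
    assert 0.0 < r.point < 1.0
    with pytest.raises(cb.ValidationError):
        cb.estimate_risk(fit, {"x": 1, "g": 7})  # unseen category


class TestCaseBaseRegression:
    def _fit(self, ds):
        return cb.CaseBaseRegression().fit(
            ds[["x"]].to_numpy(), ds["disease"].to_numpy(),
            in_case_sample=ds["in_case_sample"].to_numpy(),
            in_base_sample=ds["in_base_sample"].to_numpy())

    def test_matches_functional_api(self, scenario1_dataset):
        est = self._fit(scenario1_dataset)
        fit = cb.fit_casebase(scenario1_dataset, ["x"])
        assert est.coef_[0] == pytest.approx(fit.beta_hat[0], abs=1e-12)
        assert est.intercept_ == pytest.approx(fit.alpha_hat, abs=1e-12)
        assert est.rho_ == fit.rho.rho_hat
        p = est.predict_proba(np.array([[0.0], [1.0]]))[:, 1]
        assert p[0] == pytest.approx(cb.estimate_risk(fit, {"x": 0}).point,
                                     abs=1e-12)
        assert est.relative_risk([1.0], [0.0]).point == pytest.approx(
            cb.estimate_rr(fit, {"x": 1}, {"x": 0}).point, abs=1e-12)

    def test_sklearn_protocol(self, scenario1_dataset):
        from sklearn.base import clone
        est = cb.CaseBaseRegression(level=0.9)
        assert clone(est).get_params()["level"] == 0.9
        est.set_params(level=0.95)
        fitted = self._fit(scenario1_dataset)
        assert fitted.n_features_in_ == 1
        assert set(fitted.predict(np.array([[0.0], [1.0]]))) <= {0, 1}

    def test_cohort_mode_default_flags(self, scenario1_dataset):
        """Without sampling flags the estimator treats data as a cohort."""
        ds = scenario1_dataset
        est = cb.CaseBaseRegression().fit(ds[["x"]].to_numpy(),
                                          ds["disease"].to_numpy())
        assert est.rho_ == 1.0
        assert est.intercept_ == pytest.approx(est.alpha_star_, abs=1e-15)
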