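"""Population model: baseline-odds solving and analytic ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import casebase as cb


def test_scenario1_truths_match_printed_values(scenario1_model):
    """The solved single-binary-exposure model reproduces the published
    true risks (0.0727 / 0.1638), RR 2.2543 and logit risks."""
    tt = cb.truth_table(scenario1_model)
    assert tt.loc["0", "risk"] == pytest.approx(0.0727, abs=5e-5)
    assert tt.loc["1", "risk"] == pytest.approx(0.1638, abs=5e-5)
    assert tt.loc["1", "rr"] == pytest.approx(2.2543, abs=5e-5)
    assert tt.loc["1", "log_rr"] == pytest.approx(0.8128, abs=5e-5)
    assert tt.loc["0", "logit_risk"] == pytest.approx(-2.5465, abs=5e-5)
    assert tt.loc["1", "logit_risk"] == pytest.approx(-1.6303, abs=5e-5)
    assert tt.attrs["marginal_prevalence"] == pytest.approx(0.1, abs=1e-12)


def test_no_covariate_closed_form():
    """With beta = 0 the baseline odds is p/(1-p) exactly."""
    m = cb.solve_baseline_odds(
        [cb.CovariateSpec("x", "binary", prevalence=0.5)], {"x": 0.0}, 0.25)
    assert m.baseline_odds == pytest.approx(0.25 / 0.75, abs=1e-10)
    # q = 1, beta = 0 puts every risk at one half
    risks = m.risk({"x": [0, 1]})
    assert np.allclose(risks, 0.25)


def test_logistic_risk_identity():
    design = cb.Design([cb.CovariateSpec("x", "binary", prevalence=0.3)])
    m = cb.PopulationModel(design, log_baseline_odds=-2.5465440545013176,
                           beta=np.array([np.log(2.5)]))
    assert cb.logistic_risk(m, {"x": 1})[0] == pytest.approx(
        expit(-2.5465440545013176 + np.log(2.5)), abs=1e-15)
    assert cb.logistic_risk(m, {"x": 0})[0] == pytest.approx(
        expit(-2.5465440545013176), abs=1e-15)


def test_unknown_category_rejected(scenario1_model):
    with pytest.raises(cb.ValidationError):
        scenario1_model.risk({"x": 2})


def test_reference_profile_rr_is_one(scenario1_model):
    tt = cb.truth_table(scenario1_model)
    assert tt.loc["0", "rr"] == 1.0
    assert tt.loc["0", "log_rr"] == 0.0


def test_truth_table_requires_reference(scenario1_model):
    import pandas as pd
    with pytest.raises(cb.ValidationError):
        cb.truth_table(scenario1_model, pd.DataFrame({"x": [1.0]}))


def test_unreachable_prevalence_raises():
    # prevalence far below anything reachable within the intercept bracket
    with pytest.raises(cb.SolverError):
        cb.solve_baseline_odds(
            [cb.CovariateSpec("x", "binary", prevalence=0.5)],
            {"x": 50.0}, 1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(p=st.floats(0.05, 0.95), b=st.floats(-2.0, 2.0),
       target=st.floats(0.01, 0.6))
def test_solver_round_trip(p, b, target):
    """Recomputing the marginal prevalence from a solved model recovers the
    target, and the reference risk is below/above the marginal prevalence
    according to the sign of beta."""
    m = cb.solve_baseline_odds(
        [cb.CovariateSpec("x", "binary", prevalence=p)], {"x": b}, target)
    assert cb.marginal_prevalence(m) == pytest.approx(target, abs=1e-10)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(b=st.floats(0.1, 2.0), delta=st.floats(0.01, 1.0))
def test_risk_monotone_in_beta(b, delta):
    """Holding q fixed, increasing a beta component increases the risk at
    any profile with a positive covariate value."""
    design = cb.Design([cb.CovariateSpec("x", "binary", prevalence=0.3)])
    lo = cb.PopulationModel(design, -2.0, np.array([b]))
    hi = cb.PopulationModel(design, -2.0, np.array([b + delta]))
    assert hi.risk({"x": 1})[0] > lo.risk({"x": 1})[0]
    assert hi.risk({"x": 0})[0] == lo.risk({"x": 0})[0]


def test_categorical_score_design_truth():
    """Four-level exposure with a constant per-level log OR: logit risks are
    equally spaced and the marginal prevalence is exact."""
    m = cb.solve_baseline_odds(
        [cb.CovariateSpec("x", "categorical", probs=(0.5, 0.3, 0.1, 0.1))],
        {"x": np.log(2.5)}, 0.1, coding={"x": "score"})
    tt = cb.truth_table(m)
    spacing = np.diff(tt["logit_risk"].to_numpy())
    assert np.allclose(spacing, np.log(2.5), atol=1e-12)
    assert tt.attrs["marginal_prevalence"] == pytest.approx(0.1, abs=1e-12)


def test_continuous_quadrature_matches_monte_carlo():
    """Gauss-Hermite expectation for a normal exposure agrees with a direct
    Monte-Carlo average of the risk."""
    spec = cb.CovariateSpec("z", "continuous", dist="norm", params=(0.0, 1.0))
    m = cb.solve_baseline_odds([spec], {"z": np.log(2.5)}, 0.1)
    rng = np.random.default_rng(7)
    z = rng.normal(size=400_000)
    mc = expit(m.log_baseline_odds + np.log(2.5) * z).mean()
    assert mc == pytest.approx(0.1, abs=1e-3)


def test_rare_disease_limit_rr_approaches_or():
    """As the target prevalence shrinks, log RR converges to log OR."""
    gaps = []
    for prev in (0.1, 0.01, 0.001):
        m = cb.solve_baseline_odds(
            [cb.CovariateSpec("x", "binary", prevalence=0.3)],
            {"x": np.log(2.5)}, prev)
        tt = cb.truth_table(m)
        gaps.append(abs(tt.loc["1", "log_rr"] - np.log(2.5)))
    assert gaps[0] > gaps[1] > gaps[2]
    assert gaps[2] < 5e-3
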