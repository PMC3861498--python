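"""Study runner: engines, scenarios, aggregation and the design calculator."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import casebase as cb
from casebase._engine import batched_logistic, sample_profile_counts


def test_batched_fit_matches_statsmodels():
    """The vectorized grouped Newton fit agrees with a statsmodels GLM on
    the same counts, coefficient and covariance alike."""
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(4), [0, 1, 2, 3], [0, 1, 0, 1]])
    y = rng.integers(5, 60, size=(6, 4)).astype(float)
    m = y + rng.integers(5, 80, size=(6, 4))
    beta, cov, ok = batched_logistic(X, y, m)
    assert ok.all()
    for r in range(6):
        ref = sm.GLM(np.column_stack([y[r], m[r] - y[r]]), X,
                     family=sm.families.Binomial()).fit(tol=1e-12, maxiter=200)
        assert np.allclose(beta[r], ref.params, atol=1e-8)
        assert np.allclose(cov[r], ref.cov_params(), atol=1e-8)


def test_batched_fit_flags_degenerate_replicates():
    X = np.column_stack([np.ones(2), [0.0, 1.0]])
    y = np.array([[5.0, 0.0], [5.0, 4.0]])
    m = np.array([[10.0, 0.0], [10.0, 8.0]])  # first replicate: empty cell
    _, _, ok = batched_logistic(X, y, m)
    assert not ok[0] and ok[1]


def test_profile_count_sampler_moments():
    """Count-level recruitment matches the analytic expectations of the
    row-level Bernoulli scheme."""
    rng = np.random.default_rng(6)
    probs = np.array([0.7, 0.3])
    risks = np.array([0.0727, 0.1638])
    c = sample_profile_counts(rng, 4000, 100_000, probs, risks, 0.05, 0.005)
    recruit = 0.05 + 0.005 - 0.05 * 0.005
    for k in range(2):
        e_dis = 100_000 * probs[k] * risks[k] * recruit
        assert c["diseased"][:, k].mean() == pytest.approx(e_dis, rel=0.02)
        e_n1 = 100_000 * probs[k] * risks[k] * 0.005
        assert c["in_base"][:, k].mean() == pytest.approx(e_n1, rel=0.05)
    assert (c["overlap"] <= c["in_base"]).all()
    assert (c["in_base"] <= c["diseased"]).all()


def test_engines_agree_statistically():
    """The counts engine and the row-level engine estimate the same
    quantities; their Monte-Carlo means agree within combined error."""
    cfg = cb.builtin_scenarios()["table1"]
    a = cb.run_scenario(cfg, seed=100, replicates=400, engine="counts").table
    b = cb.run_scenario(cfg, seed=101, replicates=120, engine="subject").table
    merged = a.merge(b, on=["quantity", "method"], suffixes=("_c", "_s"))
    assert len(merged) == len(b)
    for _, row in merged.iterrows():
        tol = 4 * np.hypot(row["mc_se_mean_c"], row["mc_se_mean_s"])
        assert abs(row["mean_c"] - row["mean_s"]) < tol, row["quantity"]


def test_run_scenario_deterministic():
    cfg = cb.builtin_scenarios()["table1"]
    r1 = cb.run_scenario(cfg, seed=7, replicates=300)
    r2 = cb.run_scenario(cfg, seed=7, replicates=300)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_single_replicate_flags_variance():
    cfg = cb.builtin_scenarios()["table1"]
    rep = cb.run_scenario(cfg, seed=8, replicates=1)
    pres = rep.table[rep.table.method == "present"]
    assert pres["var_x100"].isna().all()
    assert pres["n_used"].eq(1).all()


def test_builtin_scenarios_cover_exhibits():
    scen = cb.builtin_scenarios()
    expected = {"table1", "table2", "table2_saturated", "table3",
                "interaction", "confounder", "confounder_unadjusted",
                "continuous", "low_prev_005", "low_prev_001"}
    assert expected <= set(scen)
    t1 = scen["table1"]
    assert t1.population_size == 100_000
    assert (t1.gamma, t1.tau) == (0.05, 0.005)
    assert t1.target_prevalence == 0.1
    assert t1.beta["x"] == pytest.approx(np.log(2.5))
    assert scen["table3"].beta["x2"] == pytest.approx(np.log(3.0))
    # reconstructed exhibits must say so
    assert "reconstruction" in scen["continuous"].notes
    assert "reconstruction" in scen["confounder"].notes


def test_comparator_cells_absent_for_risks():
    """Sato and Miettinen produce RRs only; no risk rows appear for them."""
    rep = cb.run_scenario(cb.builtin_scenarios()["table1"], seed=9,
                          replicates=200)
    t = rep.table
    assert t[(t.method == "sato") & t.quantity.str.startswith("logit_risk")].empty
    assert not t[(t.method == "present")
                 & t.quantity.str.startswith("logit_risk")].empty


def test_report_wide_layout():
    rep = cb.run_scenario(cb.builtin_scenarios()["table1"], seed=10,
                          replicates=100)
    wide = rep.to_wide()
    assert list(wide.columns[:2]) == ["statistic", "quantity"]
    assert set(wide["statistic"]) == {"mean", "var_x100", "coverage",
                                      "ci_length"}
    assert {"present", "sato", "miettinen"} <= set(wide.columns)


def test_mc_standard_errors_reported():
    rep = cb.run_scenario(cb.builtin_scenarios()["table1"], seed=11,
                          replicates=300)
    pres = rep.table[rep.table.method == "present"]
    assert (pres["mc_se_mean"] > 0).all()
    assert (pres["mc_se_coverage"] > 0).all()


def test_interaction_scenario_recovers_product_term():
    rep = cb.run_scenario(cb.builtin_scenarios()["interaction"], seed=12,
                          replicates=500)
    row = rep.table.query("method == 'present' and quantity == 'logOR_x1:x2'")
    assert abs(row["mean"].iloc[0] - np.log(2.0)) < 4 * row["mc_se_mean"].iloc[0]


def test_unadjusted_confounder_shows_bias():
    rep = cb.run_scenario(cb.builtin_scenarios()["confounder_unadjusted"],
                          seed=13, replicates=500)
    row = rep.table.query("method == 'present' and quantity == 'logOR_x'")
    # crude log OR is pulled away from the conditional truth 0.9163
    assert row["mean"].iloc[0] - row["truth"].iloc[0] > 0.15
    assert row["coverage"].iloc[0] < 0.85


class TestPlan:
    def test_base_sample_arithmetic(self):
        """450 expected non-diseased base members at prevalence 0.1 imply
        n1 = 50 and the binomial CI ratio exp(2 * 1.96 * se(50, 450))."""
        out = cb.plan(n_distinct=500, prevalence=0.1, diseased_fraction=0.1)
        assert out["expected_n1"] == pytest.approx(50.0, rel=1e-12)
        se = np.sqrt(1 / 50 + 1 / 450)
        assert out["ci_ratio_prevalence_odds"] == pytest.approx(
            np.exp(2 * 1.959964 * se), rel=1e-6)

    def test_common_disease_small_study(self):
        """200 distinct subjects (100/100) and prevalence > 0.05 give an
        expected n1 above 5."""
        out = cb.plan(n_distinct=200, prevalence=0.05, diseased_fraction=0.5)
        assert out["expected_n1"] > 5
        assert not out["low_n1_warning"]

    def test_large_study_limit(self):
        out = cb.plan(n_distinct=10_000_000, prevalence=0.1)
        assert out["ci_ratio_prevalence_odds"] == pytest.approx(1.0, abs=1e-2)

    def test_warning_when_n1_below_one(self):
        out = cb.plan(n_distinct=100, prevalence=0.005)
        assert out["low_n1_warning"]

    def test_input_validation(self):
        with pytest.raises(cb.ValidationError):
            cb.plan(1, 0.1)
        with pytest.raises(cb.ValidationError):
            cb.plan(100, 1.5)
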