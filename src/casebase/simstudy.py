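"""Monte-Carlo study runner and design-precision calculator.

``run_scenario`` repeats the full pipeline — simulate a population from a
logistic truth model, draw a case-base sample, apply each estimator — and
aggregates per-quantity summaries in the layout of the simulation tables:
mean estimate (log/logit scale), empirical variance x100, 95%-CI coverage
against the analytic truth, and average CI length, each with a Monte-Carlo
standard error. ``builtin_scenarios`` provides the standard settings (one
binary exposure; a four-level exposure fitted with a constant per-level OR
or saturated; two binary exposures with and without interaction; a
confounder; a continuous exposure; lower prevalences).

Two engines produce identical science: a fast vectorized engine that
simulates per-profile sufficient counts and fits all replicates at once
(discrete covariates), and a row-level engine that materializes each
population and dataset (needed for continuous exposures).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._engine import batched_logistic, sample_profile_counts
from .design import CovariateSpec, Design, profile_label
from .errors import CaseBaseError, ValidationError
from .estimator import _fit_logistic_matrix
from .population import PopulationModel, solve_baseline_odds, truth_table
from .sampling import (SamplingDesign, draw_case_base_sample,
                       simulate_population, tabulate_counts)

__all__ = [
    "ScenarioConfig",
    "StudyReport",
    "run_scenario",
    "builtin_scenarios",
    "plan",
]

_Z95 = norm.ppf(0.975)

LOG_OR_25 = float(np.log(2.5))
LOG_OR_3 = float(np.log(3.0))


@dataclass
class ScenarioConfig:
    """Configuration of one Monte-Carlo scenario.

    ``beta`` holds the true log odds ratios keyed by truth-design column;
    the truth design encodes ``covariates`` with ``coding`` (categorical
    covariates default to dummy coding; ``"score"`` imposes a constant OR
    per adjacent level) and optional ``interactions``. The fitted model may
    use a different coding, a covariate subset or extra interaction columns
    (``fit_*`` fields), which is how misspecification scenarios are built.
    """

    name: str
    covariates: list[CovariateSpec]
    beta: dict[str, float]
    target_prevalence: float
    coding: dict[str, str] = field(default_factory=dict)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    joint: pd.DataFrame | None = None
    population_size: int = 100_000
    gamma: float = 0.05
    tau: float = 0.005
    replicates: int = 10_000
    fit_covariates: list[str] | None = None
    fit_coding: dict[str, str] | None = None
    fit_interactions: list[tuple[str, str]] | None = None
    methods: tuple[str, ...] = ("present", "sato", "miettinen")
    rr_profiles: pd.DataFrame | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    def truth_design(self) -> Design:
        return Design(self.covariates, coding=self.coding,
                      interactions=self.interactions, joint=self.joint)

    def truth_model(self) -> PopulationModel:
        return solve_baseline_odds(self.truth_design(), self.beta,
                                   self.target_prevalence)

    def fit_design(self) -> Design:
        names = self.fit_covariates
        covs = (self.covariates if names is None
                else [c for c in self.covariates if c.name in names])
        if names is not None and len(covs) != len(names):
            missing = set(names) - {c.name for c in covs}
            raise ValidationError(f"unknown fit covariates {sorted(missing)}")
        coding = self.fit_coding if self.fit_coding is not None else self.coding
        inter = (self.fit_interactions if self.fit_interactions is not None
                 else self.interactions)
        return Design(covs, coding={k: v for k, v in coding.items()
                                    if k in {c.name for c in covs}},
                      interactions=inter)


@dataclass
class StudyReport:
    """Per-(quantity, method) Monte-Carlo summaries for one scenario."""

    scenario: str
    table: pd.DataFrame          # long: quantity, method, truth, stats, MC se
    truth: pd.DataFrame | None   # analytic truth table of the scenario
    replicates: int
    seed: int | None
    notes: str = ""

    def to_wide(self, decimals: int | None = 4) -> pd.DataFrame:
        """Table-shaped view: blocks of statistics, methods as columns."""
        blocks = []
        for stat in ("mean", "var_x100", "coverage", "ci_length"):
            w = self.table.pivot(index="quantity", columns="method", values=stat)
            w.insert(0, "statistic", stat)
            blocks.append(w.reset_index())
        out = pd.concat(blocks, ignore_index=True)
        out = out[["statistic", "quantity"]
                  + [c for c in out.columns if c not in ("statistic", "quantity")]]
        if decimals is not None:
            num = out.select_dtypes(float).columns
            out[num] = out[num].round(decimals)
        return out


# ---------------------------------------------------------------------------
# quantity bookkeeping
# ---------------------------------------------------------------------------

def _or_truth(column: str, model: PopulationModel) -> float:
    """True log OR for a fitted model column, when derivable."""
    cols = model.design.columns
    if column in cols:
        return float(model.beta[cols.index(column)])
    m = re.fullmatch(r"(.+)\[(\d+)\]", column)
    if m and m.group(1) in cols:
        # dummy column fitted against a score-coded truth: level k vs 0
        return float(model.beta[cols.index(m.group(1))]) * int(m.group(2))
    if ":" in column:
        return 0.0  # truth has no interaction term
    return np.nan


def _fit_profiles(config: ScenarioConfig, fitd: Design) -> pd.DataFrame:
    if config.rr_profiles is not None:
        return config.rr_profiles.copy()
    finite = fitd.finite_profiles()
    if finite is None:
        raise ValidationError(
            f"{config.name}: rr_profiles must be given for continuous exposures")
    profiles = finite[0]
    profiles.index = pd.Index(
        [profile_label(r, fitd.covariates) for _, r in profiles.iterrows()])
    return profiles


def _reference_index(profiles: pd.DataFrame, fitd: Design) -> int:
    ref = fitd.reference_profile()
    names = [c.name for c in fitd.covariates]
    hit = np.flatnonzero(
        (profiles[names].to_numpy(dtype=float) == ref[names].to_numpy()).all(axis=1))
    if hit.size != 1:
        raise ValidationError("profiles must contain the reference profile once")
    return int(hit[0])


def _truth_logits(config: ScenarioConfig, profiles: pd.DataFrame,
                  model: PopulationModel) -> np.ndarray:
    """True logit risks at fit profiles, excluded covariates at reference."""
    full = profiles.copy()
    for cov in config.covariates:
        if cov.name not in full.columns:
            full[cov.name] = cov.reference
    return np.asarray(model.linear_predictor(full), dtype=float)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _summarize(quantity: str, method: str, truth: float,
               est: np.ndarray, se: np.ndarray | None,
               valid: np.ndarray) -> dict:
    valid = valid & np.isfinite(est)
    if se is not None:
        valid = valid & np.isfinite(se)
    n = int(valid.sum())
    row = {"quantity": quantity, "method": method, "truth": truth,
           "n_used": n, "n_failed": int(valid.size - n),
           "mean": np.nan, "var_x100": np.nan, "coverage": np.nan,
           "ci_length": np.nan, "mc_se_mean": np.nan, "mc_se_var_x100": np.nan,
           "mc_se_coverage": np.nan, "mc_se_ci_length": np.nan}
    if n == 0:
        return row
    e = est[valid]
    row["mean"] = float(e.mean())
    if n > 1:
        v = float(e.var(ddof=1))
        row["var_x100"] = 100.0 * v
        row["mc_se_mean"] = float(np.sqrt(v / n))
        # normal-theory approximation to the sampling error of a variance
        row["mc_se_var_x100"] = 100.0 * v * float(np.sqrt(2.0 / (n - 1)))
    if se is not None:
        s = se[valid]
        length = 2.0 * _Z95 * s
        row["ci_length"] = float(length.mean())
        if n > 1:
            row["mc_se_ci_length"] = float(length.std(ddof=1) / np.sqrt(n))
        if np.isfinite(truth):
            inside = np.abs(e - truth) <= _Z95 * s
            c = float(inside.mean())
            row["coverage"] = c
            row["mc_se_coverage"] = float(np.sqrt(max(c * (1 - c), 0.0) / n))
    return row


# ---------------------------------------------------------------------------
# vectorized counts engine (discrete covariates)
# ---------------------------------------------------------------------------

def _run_counts(config: ScenarioConfig, model: PopulationModel,
                seed: int | None, R: int) -> list[dict]:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    truthd = model.design
    fitd = config.fit_design()
    profiles_all, probs = truthd.joint_support()
    risks = np.asarray(model.risk(profiles_all), dtype=float)
    X_all = fitd.encode(profiles_all)
    fit_profiles = _fit_profiles(config, fitd)
    ref = _reference_index(fit_profiles, fitd)
    Xq = fitd.encode(fit_profiles)
    labels = list(fit_profiles.index.astype(str))
    lt = _truth_logits(config, fit_profiles, model)

    counts = sample_profile_counts(rng, R, config.population_size, probs,
                                   risks, config.gamma, config.tau)
    D, O, C = counts["diseased"], counts["in_base"], counts["nondiseased"]
    n_D = D.sum(axis=1)
    n1 = O.sum(axis=1)
    has_rho = n1 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(has_rho, n1 / np.maximum(n_D, 1), np.nan)
        vlr = (1.0 - rho) / (np.maximum(n_D, 1) * rho)
        log_rho = np.log(rho)

    rows: list[dict] = []
    p = len(fitd.columns)
    Xi = np.column_stack([np.ones(len(profiles_all)), X_all])

    if "present" in config.methods:
        beta, V, ok = batched_logistic(Xi, D, D + C)
        slopes = beta[:, 1:]
        for j, col in enumerate(fitd.columns):
            rows.append(_summarize(
                f"logOR_{col}", "present", _or_truth(col, model),
                beta[:, 1 + j], np.sqrt(V[:, 1 + j, 1 + j]), ok))
        alpha_hat = beta[:, 0] + log_rho
        logits = alpha_hat[:, None] + slopes @ Xq.T           # (R, Q)
        zq = np.column_stack([np.ones(len(labels)), Xq])      # (Q, 1+p)
        var_logit = np.einsum("qi,rij,qj->rq", zq, V, zq) + vlr[:, None]
        pq = expit(logits)
        ok_rho = ok & has_rho
        for q, lab in enumerate(labels):
            rows.append(_summarize(
                f"logit_risk_{lab}", "present", lt[q],
                logits[:, q], np.sqrt(var_logit[:, q]), ok_rho))
        lrr_truth = np.log(expit(lt)) - np.log(expit(lt[ref]))
        for q, lab in enumerate(labels):
            if q == ref:
                continue
            p1, p0 = pq[:, q], pq[:, ref]
            est = np.log(p1) - np.log(p0)
            c = (1.0 - p1) - (1.0 - p0)
            h = np.empty((R, 1 + p))
            h[:, 0] = c
            h[:, 1:] = ((1.0 - p1)[:, None] * Xq[q]
                        - (1.0 - p0)[:, None] * Xq[ref])
            var = np.einsum("ri,rij,rj->r", h, V, h) + c * c * vlr
            rows.append(_summarize(f"logRR_{lab}", "present", lrr_truth[q],
                                   est, np.sqrt(var), ok_rho))

    # collapse truth profiles onto fit profiles for the 2x2 comparators
    if {"sato", "miettinen", "duplication"} & set(config.methods):
        fit_names = [c.name for c in fitd.covariates]
        key_all = [profile_label(r, fitd.covariates)
                   for _, r in profiles_all[fit_names].iterrows()]
        group = np.array([labels.index(k) for k in key_all])
        Q = len(labels)
        A = np.zeros((R, Q)); Ob = np.zeros((R, Q)); Cn = np.zeros((R, Q))
        for g in range(Q):
            sel = group == g
            A[:, g] = D[:, sel].sum(axis=1)
            Ob[:, g] = O[:, sel].sum(axis=1)
            Cn[:, g] = C[:, sel].sum(axis=1)
        base = Ob + Cn
        lrr_truth = np.log(expit(lt)) - np.log(expit(lt[ref]))

        if "sato" in config.methods:
            for q, lab in enumerate(labels):
                if q == ref:
                    continue
                a1, a0 = A[:, q], A[:, ref]
                b1, b0 = Cn[:, q], Cn[:, ref]
                sub_n1 = Ob[:, q] + Ob[:, ref]
                sub_nD = a1 + a0
                valid = (a1 > 0) & (a0 > 0) & (b1 > 0) & (b0 > 0) & (sub_n1 > 0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    rho_s = sub_n1 / sub_nD
                    p1 = expit(np.log(a1 / b1) + np.log(rho_s))
                    p0 = expit(np.log(a0 / b0) + np.log(rho_s))
                    est = np.log(p1) - np.log(p0)
                    c = (1.0 - p1) - (1.0 - p0)
                    var = ((1.0 - p1) ** 2 * (1.0 / a1 + 1.0 / b1)
                           + (1.0 - p0) ** 2 * (1.0 / a0 + 1.0 / b0)
                           + c * c * (1.0 - rho_s) / (sub_nD * rho_s))
                rows.append(_summarize(f"logRR_{lab}", "sato", lrr_truth[q],
                                       est, np.sqrt(var), valid))

        if "miettinen" in config.methods:
            for q, lab in enumerate(labels):
                if q == ref:
                    continue
                a1, a0 = A[:, q], A[:, ref]
                B1, B0 = base[:, q], base[:, ref]
                valid = (a1 > 0) & (a0 > 0) & (B1 > 0) & (B0 > 0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    est = np.log(a1 / a0) - np.log(B1 / B0)
                    var = (1.0 / a1 + 1.0 / a0 + 1.0 / B1 + 1.0 / B0
                           - 2.0 * Ob[:, q] / (a1 * B1)
                           - 2.0 * Ob[:, ref] / (a0 * B0))
                rows.append(_summarize(f"logRR_{lab}", "miettinen",
                                       lrr_truth[q], est, np.sqrt(var), valid))

        if "duplication" in config.methods:
            beta_d, V_d, ok_d = batched_logistic(Xi, D, D + C + O)
            for q, lab in enumerate(labels):
                if q == ref:
                    continue
                z = np.concatenate([[0.0], Xq[q] - Xq[ref]])
                est = beta_d @ z
                var = np.einsum("i,rij,j->r", z, V_d, z)
                rows.append(_summarize(f"logRR_{lab}", "duplication",
                                       lrr_truth[q], est, np.sqrt(var),
                                       ok_d & has_rho))
    return rows


# ---------------------------------------------------------------------------
# row-level engine (continuous covariates or cross-checking)
# ---------------------------------------------------------------------------

def _run_subject(config: ScenarioConfig, model: PopulationModel,
                 seed: int | None, R: int) -> list[dict]:
    fitd = config.fit_design()
    fit_profiles = _fit_profiles(config, fitd)
    ref = _reference_index(fit_profiles, fitd)
    Xq = fitd.encode(fit_profiles)
    labels = list(fit_profiles.index.astype(str))
    lt = _truth_logits(config, fit_profiles, model)
    lrr_truth = np.log(expit(lt)) - np.log(expit(lt[ref]))
    p = len(fitd.columns)
    design = SamplingDesign(population_size=config.population_size,
                            gamma=config.gamma, tau=config.tau)
    discrete = all(c.kind != "continuous" for c in fitd.covariates)

    store: dict[tuple[str, str], dict] = {}

    def rec(method: str, quantity: str, truth: float, est: float, se: float,
            valid: bool) -> None:
        d = store.setdefault((method, quantity),
                             {"truth": truth,
                              "est": np.full(R, np.nan),
                              "se": np.full(R, np.nan),
                              "valid": np.zeros(R, dtype=bool)})
        d["est"][r] = est
        d["se"][r] = se
        d["valid"][r] = valid

    children = np.random.SeedSequence(seed).spawn(R)
    for r in range(R):
        pop_seed, sample_seed = children[r].spawn(2)
        pop = simulate_population(model, config.population_size, pop_seed)
        try:
            ds = draw_case_base_sample(pop, design, sample_seed)
        except CaseBaseError:
            continue
        counts = tabulate_counts(ds)
        X = fitd.encode(ds)
        n1, nD = counts.n1, counts.n_D
        rho = n1 / nD if n1 > 0 else np.nan
        vlr = (1 - rho) / (nD * rho) if n1 > 0 else np.nan

        if "present" in config.methods:
            try:
                lf = _fit_logistic_matrix(X, ds["disease"].to_numpy(dtype=float),
                                          columns=fitd.columns)
            except CaseBaseError:
                lf = None
            if lf is not None:
                V = lf.covariance
                for j, col in enumerate(fitd.columns):
                    rec("present", f"logOR_{col}", _or_truth(col, model),
                        lf.beta[j], np.sqrt(V[1 + j, 1 + j]), True)
                if n1 > 0:
                    alpha_hat = lf.alpha_star + np.log(rho)
                    logits = alpha_hat + Xq @ lf.beta
                    pq = expit(logits)
                    for q, lab in enumerate(labels):
                        z = np.concatenate([[1.0], Xq[q]])
                        var = z @ V @ z + vlr
                        rec("present", f"logit_risk_{lab}", lt[q],
                            logits[q], np.sqrt(var), True)
                        if q != ref:
                            p1, p0 = pq[q], pq[ref]
                            c = (1 - p1) - (1 - p0)
                            h = np.concatenate(
                                [[c], (1 - p1) * Xq[q] - (1 - p0) * Xq[ref]])
                            rec("present", f"logRR_{lab}", lrr_truth[q],
                                np.log(p1 / p0), np.sqrt(h @ V @ h + c * c * vlr),
                                True)

        if discrete and {"sato", "miettinen"} & set(config.methods):
            key = [profile_label(row, fitd.covariates)
                   for _, row in ds[[c.name for c in fitd.covariates]].iterrows()]
            key = np.array(key)
            d_mask = ds["disease"].to_numpy() == 1
            b_mask = ds["in_base_sample"].to_numpy() == 1
            for q, lab in enumerate(labels):
                if q == ref:
                    continue
                sel1, sel0 = key == labels[q], key == labels[ref]
                a1, a0 = int((d_mask & sel1).sum()), int((d_mask & sel0).sum())
                B1, B0 = int((b_mask & sel1).sum()), int((b_mask & sel0).sum())
                o1 = int((d_mask & b_mask & sel1).sum())
                o0 = int((d_mask & b_mask & sel0).sum())
                b1, b0 = B1 - o1, B0 - o0
                if "sato" in config.methods:
                    okc = min(a1, a0, b1, b0) > 0 and (o1 + o0) > 0
                    if okc:
                        rho_s = (o1 + o0) / (a1 + a0)
                        p1 = expit(np.log(a1 / b1) + np.log(rho_s))
                        p0 = expit(np.log(a0 / b0) + np.log(rho_s))
                        c = (1 - p1) - (1 - p0)
                        var = ((1 - p1) ** 2 * (1 / a1 + 1 / b1)
                               + (1 - p0) ** 2 * (1 / a0 + 1 / b0)
                               + c * c * (1 - rho_s) / ((a1 + a0) * rho_s))
                        rec("sato", f"logRR_{lab}", lrr_truth[q],
                            np.log(p1 / p0), np.sqrt(var), True)
                if "miettinen" in config.methods and min(a1, a0, B1, B0) > 0:
                    var_m = (1 / a1 + 1 / a0 + 1 / B1 + 1 / B0
                             - 2 * o1 / (a1 * B1) - 2 * o0 / (a0 * B0))
                    rec("miettinen", f"logRR_{lab}", lrr_truth[q],
                        np.log(a1 / a0) - np.log(B1 / B0), np.sqrt(var_m), True)

        if "duplication" in config.methods and n1 > 0:
            dup_mask = (ds["disease"] == 1) & (ds["in_base_sample"] == 1)
            copies = ds.loc[dup_mask].copy()
            copies["disease"] = 0
            expanded = pd.concat([ds, copies], ignore_index=True)
            try:
                lf = _fit_logistic_matrix(
                    fitd.encode(expanded),
                    expanded["disease"].to_numpy(dtype=float),
                    columns=fitd.columns)
            except CaseBaseError:
                lf = None
            if lf is not None:
                for q, lab in enumerate(labels):
                    if q == ref:
                        continue
                    z = np.concatenate([[0.0], Xq[q] - Xq[ref]])
                    rec("duplication", f"logRR_{lab}", lrr_truth[q],
                        z[1:] @ lf.beta, np.sqrt(z @ lf.covariance @ z), True)

    rows = []
    for (method, quantity), d in store.items():
        rows.append(_summarize(quantity, method, d["truth"], d["est"],
                               d["se"], d["valid"]))
    return rows


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def run_scenario(config: ScenarioConfig, seed: int | None = None,
                 replicates: int | None = None,
                 engine: str = "auto") -> StudyReport:
    """Run one Monte-Carlo scenario and aggregate the study report.

    ``engine="counts"`` simulates per-profile sufficient statistics and
    fits all replicates at once (requires discrete covariates);
    ``"subject"`` materializes each population and dataset row by row;
    ``"auto"`` picks "counts" whenever possible. Replicates with an
    inestimable quantity (no diseased subject in the base sample, empty or
    separated cells) are excluded from that quantity's aggregation and
    tallied in ``n_failed``.
    """
    R = int(replicates if replicates is not None else config.replicates)
    if R < 1:
        raise ValidationError("replicates must be >= 1")
    model = config.truth_model()
    discrete = (model.design.finite_profiles() is not None
                and all(c.kind != "continuous"
                        for c in config.fit_design().covariates))
    if engine == "auto":
        engine = "counts" if discrete else "subject"
    if engine == "counts" and not discrete:
        raise ValidationError("counts engine requires discrete covariates")
    if engine not in ("counts", "subject"):
        raise ValidationError("engine must be 'auto', 'counts' or 'subject'")
    rows = (_run_counts if engine == "counts" else _run_subject)(
        config, model, seed, R)
    table = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(config.methods)}
    table = table.sort_values(
        ["quantity", "method"],
        key=lambda s: s.map(order) if s.name == "method" else s,
    ).reset_index(drop=True)
    try:
        truth = truth_table(model)
    except ValidationError:
        truth = None
    return StudyReport(scenario=config.name, table=table, truth=truth,
                       replicates=R, seed=seed, notes=config.notes)


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Standard simulation scenarios.

    The three main settings share a population of 100,000, case-sampling
    probability 0.05, base-sampling probability 0.005 and marginal disease
    prevalence 0.1. Variants whose exhibit parameters are not printed in
    the main text (continuous exposure, interaction strength, confounder
    structure) are reconstructions and say so in ``notes``.
    """
    x_bin = CovariateSpec("x", "binary", prevalence=0.3)
    scenarios = {}
    scenarios["table1"] = ScenarioConfig(
        name="table1", covariates=[x_bin], beta={"x": LOG_OR_25},
        target_prevalence=0.1)
    four = CovariateSpec("x", "categorical", probs=(0.5, 0.3, 0.1, 0.1))
    scenarios["table2"] = ScenarioConfig(
        name="table2", covariates=[four], coding={"x": "score"},
        beta={"x": LOG_OR_25}, target_prevalence=0.1)
    scenarios["table2_saturated"] = ScenarioConfig(
        name="table2_saturated", covariates=[four], coding={"x": "score"},
        beta={"x": LOG_OR_25}, target_prevalence=0.1,
        fit_coding={"x": "dummy"},
        notes="four-level exposure fitted without the constant-OR assumption")
    two = [CovariateSpec("x1", "binary", prevalence=0.3),
           CovariateSpec("x2", "binary", prevalence=0.4)]
    scenarios["table3"] = ScenarioConfig(
        name="table3", covariates=two,
        beta={"x1": LOG_OR_25, "x2": LOG_OR_3}, target_prevalence=0.1)
    scenarios["interaction"] = ScenarioConfig(
        name="interaction", covariates=two,
        interactions=[("x1", "x2")],
        beta={"x1": LOG_OR_25, "x2": LOG_OR_3, "x1:x2": float(np.log(2.0))},
        target_prevalence=0.1,
        notes="reconstruction: interaction log OR set to log 2, "
              "exhibit parameters unavailable")
    joint = pd.DataFrame({
        "x": [0.0, 1.0, 0.0, 1.0],
        "c": [0.0, 0.0, 1.0, 1.0],
        # P(c=1)=0.4; P(x=1|c=0)=0.2, P(x=1|c=1)=0.4
        "prob": [0.48, 0.12, 0.24, 0.16],
    })
    conf = [CovariateSpec("x", "binary", prevalence=0.28),
            CovariateSpec("c", "binary", prevalence=0.4)]
    scenarios["confounder"] = ScenarioConfig(
        name="confounder", covariates=conf, joint=joint,
        beta={"x": LOG_OR_25, "c": LOG_OR_3}, target_prevalence=0.1,
        notes="reconstruction: binary confounder (prevalence 0.4, disease "
              "log OR log 3) with exposure prevalence 0.2/0.4 by stratum")
    scenarios["confounder_unadjusted"] = replace(
        scenarios["confounder"], name="confounder_unadjusted",
        fit_covariates=["x"],
        notes=scenarios["confounder"].notes + "; fitted without adjustment")
    scenarios["continuous"] = ScenarioConfig(
        name="continuous",
        covariates=[CovariateSpec("x", "continuous", dist="norm",
                                  params=(0.0, 1.0))],
        beta={"x": LOG_OR_25}, target_prevalence=0.1,
        methods=("present", "duplication"),
        rr_profiles=pd.DataFrame({"x": [0.0, 1.0]}, index=["0", "1"]),
        notes="reconstruction: standard-normal exposure, per-unit log OR "
              "log 2.5 (exhibit distribution unavailable)")
    scenarios["low_prev_005"] = replace(
        scenarios["table1"], name="low_prev_005", target_prevalence=0.05)
    scenarios["low_prev_001"] = replace(
        scenarios["table1"], name="low_prev_001", target_prevalence=0.01)
    return scenarios


def plan(n_distinct: int, prevalence: float,
         diseased_fraction: float = 0.5) -> dict:
    """Design-precision calculator for a planned case-base study.

    Given the total number of distinct recruited subjects, the disease
    prevalence and the diseased/non-diseased allocation, returns the
    expected number of diseased subjects in the base sample (``expected_n1``
    — the quantity that drives the precision of risk and RR estimates) and
    the expected ratio of the upper to the lower 95% confidence bound of
    the prevalence odds estimated from the base sample.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValidationError("prevalence must lie in (0, 1)")
    if n_distinct < 2 or not 0.0 < diseased_fraction < 1.0:
        raise ValidationError("need n_distinct >= 2 and a proper allocation")
    n_nondiseased = n_distinct * (1.0 - diseased_fraction)
    # non-diseased subjects enter only through base sampling, so the base
    # sample holds ~n_nondiseased non-diseased and prevalence-proportional
    # diseased members
    expected_n1 = n_nondiseased * prevalence / (1.0 - prevalence)
    se = float(np.sqrt(1.0 / expected_n1 + 1.0 / n_nondiseased))
    return {
        "expected_n1": float(expected_n1),
        "ci_ratio_prevalence_odds": float(np.exp(2.0 * _Z95 * se)),
        "low_n1_warning": bool(expected_n1 < 1.0),
    }
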