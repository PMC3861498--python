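"""Population disease model and ground truth.

The study population is assumed to follow a logistic disease model

    logit P(D = 1 | x) = log q + x beta,

where ``q`` is the baseline disease odds (the disease odds at the reference
exposure profile x = 0) and ``beta`` holds log odds ratios, one per model
column. Scenarios are specified by the covariate distribution, the odds
ratios and a target marginal disease prevalence; ``solve_baseline_odds``
finds the unique ``q`` whose population-averaged risk matches that
prevalence, and ``truth_table`` derives the per-profile risks and relative
risks that simulation studies use as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .design import CovariateSpec, Design, profile_label
from .errors import SolverError, ValidationError

__all__ = [
    "PopulationModel",
    "logistic_risk",
    "solve_baseline_odds",
    "marginal_prevalence",
    "truth_table",
]

# bracket for the log baseline odds; expit is monotone in the intercept so
# the root is unique whenever one exists in the bracket
_BRACKET = (-40.0, 10.0)


@dataclass
class PopulationModel:
    """Logistic disease model for the study population."""

    design: Design
    log_baseline_odds: float
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.design.n_columns,):
            raise ValidationError(
                f"beta has length {self.beta.size}, design has "
                f"{self.design.n_columns} columns {self.design.columns}")
        if not np.isfinite(self.beta).all() or not np.isfinite(self.log_baseline_odds):
            raise ValidationError("model parameters must be finite")

    @property
    def baseline_odds(self) -> float:
        return float(np.exp(self.log_baseline_odds))

    def linear_predictor(self, data: pd.DataFrame | dict) -> np.ndarray:
        return self.log_baseline_odds + self.design.encode(data) @ self.beta

    def risk(self, data: pd.DataFrame | dict) -> np.ndarray:
        return expit(self.linear_predictor(data))


def logistic_risk(model: PopulationModel, x: pd.DataFrame | dict) -> np.ndarray:
    """Disease risk expit(log q + x beta) for one or more covariate rows."""
    return model.risk(x)


def _as_beta(design: Design, beta) -> np.ndarray:
    if isinstance(beta, Mapping):
        missing = [c for c in design.columns if c not in beta]
        if missing:
            raise ValidationError(f"beta missing entries for columns {missing}")
        return np.array([float(beta[c]) for c in design.columns])
    arr = np.asarray(beta, dtype=float).ravel()
    if arr.size != design.n_columns:
        raise ValidationError(
            f"beta has length {arr.size}, expected {design.n_columns}")
    return arr


def solve_baseline_odds(covariates: Sequence[CovariateSpec] | Design,
                        beta,
                        target_prevalence: float,
                        *,
                        coding: dict[str, str] | None = None,
                        interactions: Sequence[tuple[str, str]] = (),
                        joint: pd.DataFrame | None = None,
                        tol: float = 1e-12) -> PopulationModel:
    """Solve for the baseline odds giving a target marginal prevalence.

    Finds log q in [−40, 10] such that E_x[expit(log q + x beta)] equals
    ``target_prevalence`` to within ``tol``, where the expectation runs over
    the covariates' joint distribution (exact for finite support, quadrature
    for normal covariates, fixed-seed Monte-Carlo otherwise).

    ``beta`` may be an array aligned with the design columns or a mapping
    from column name to log odds ratio.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValidationError("target prevalence must lie in (0, 1)")
    design = covariates if isinstance(covariates, Design) else Design(
        covariates, coding=coding, interactions=interactions, joint=joint)
    b = _as_beta(design, beta)
    profiles, weights = design.joint_support()
    eta = design.encode(profiles) @ b

    def f(a: float) -> float:
        return float(weights @ expit(a + eta)) - target_prevalence

    lo, hi = _BRACKET
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise SolverError(
            f"no root for baseline log odds in [{lo}, {hi}]: "
            f"f({lo}) = {flo:.3e}, f({hi}) = {fhi:.3e}; the target prevalence "
            "may be unreachable for this covariate distribution")
    a = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    if abs(f(a)) > tol:
        raise SolverError(
            f"baseline-odds solver residual {f(a):.2e} exceeds tolerance {tol:.0e}")
    return PopulationModel(design=design, log_baseline_odds=float(a), beta=b)


def marginal_prevalence(model: PopulationModel) -> float:
    """Population-averaged disease risk implied by the model."""
    profiles, weights = model.design.joint_support()
    return float(weights @ model.risk(profiles))


def truth_table(model: PopulationModel,
                profiles: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-profile true risks and relative risks.

    Relative risks compare each profile with the reference profile (all
    covariates at their reference value), which must be included. Returns a
    frame indexed by a compact profile label with columns ``risk``,
    ``logit_risk``, ``rr``, ``log_rr`` plus covariate values, and stores the
    marginal prevalence in ``attrs["marginal_prevalence"]``.
    """
    design = model.design
    if profiles is None:
        finite = design.finite_profiles()
        if finite is None:
            raise ValidationError(
                "profiles must be given explicitly for continuous covariates")
        profiles = finite[0]
    profiles = profiles.reset_index(drop=True)
    risk = model.risk(profiles)
    ref = design.reference_profile()
    ref_risk = float(model.risk(ref)[0])
    match = np.flatnonzero(
        (profiles[[c.name for c in design.covariates]].to_numpy()
         == ref.to_numpy()).all(axis=1))
    if match.size == 0:
        raise ValidationError("profiles must include the reference profile")
    out = profiles.copy()
    out["risk"] = risk
    out["logit_risk"] = logit(risk)
    out["rr"] = risk / ref_risk
    out["log_rr"] = np.log(out["rr"])
    # the reference profile's RR is exactly 1 by construction
    out.loc[match, ["rr", "log_rr"]] = [1.0, 0.0]
    out.index = pd.Index(
        [profile_label(row, design.covariates) for _, row in profiles.iterrows()],
        name="profile")
    out.attrs["marginal_prevalence"] = marginal_prevalence(model)
    return out
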