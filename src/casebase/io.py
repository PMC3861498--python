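"""Dataset, scenario-config and report I/O.

Datasets travel as plain CSV with one row per distinct recruited subject:

    subject_id,<covariate columns>,disease,in_case_sample,in_base_sample

with ``disease`` and both membership flags strictly 0/1. Scenario
configurations are YAML (schema below); study reports are written as a CSV
mirroring the simulation-table layout (4 decimal places) plus a JSON
sidecar carrying full precision, Monte-Carlo standard errors and failure
tallies. Every CLI run also emits a JSON run manifest sufficient to
reproduce it.

Scenario YAML schema::

    name: table1                    # optional label
    prevalence: 0.1                 # target marginal disease prevalence
    population_size: 100000
    gamma: 0.05                     # case-sampling probability
    tau: 0.005                      # base-sampling probability
    replicates: 10000
    covariates:
      - {name: x, kind: binary, prevalence: 0.3}
      - {name: g, kind: categorical, probs: [0.5, 0.3, 0.1, 0.1],
         coding: score}             # coding: dummy (default) | score
      - {name: z, kind: continuous, dist: norm, params: [0.0, 1.0]}
    odds_ratios: {x: 2.5}           # or log_odds_ratios: {x: 0.9163}
    interactions: [[x1, x2]]        # optional product columns
    methods: [present, sato, miettinen]
    fit:                            # optional fitted-model overrides
      covariates: [x]
      coding: {g: dummy}
      interactions: []
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CovariateSpec
from .errors import ValidationError
from .estimator import CaseBaseFit
from .sampling import FLAG_COLUMNS, validate_dataset
from .simstudy import ScenarioConfig, StudyReport

__all__ = [
    "read_dataset",
    "write_dataset",
    "scenario_from_dict",
    "read_scenario_config",
    "write_report",
    "fit_to_dict",
    "RunManifest",
]


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a case-base dataset CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    missing = [c for c in FLAG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    validate_dataset(df)
    return df


def write_dataset(dataset: pd.DataFrame, path) -> None:
    cols = ([c for c in dataset.columns if c not in FLAG_COLUMNS]
            + FLAG_COLUMNS)
    dataset[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

def _covariate_from_dict(d: dict) -> tuple[CovariateSpec, str | None]:
    d = dict(d)
    coding = d.pop("coding", None)
    try:
        name, kind = d.pop("name"), d.pop("kind")
    except KeyError as exc:
        raise ValidationError(f"covariate entry missing {exc}") from exc
    if kind == "binary":
        spec = CovariateSpec(name, "binary", prevalence=d.pop("prevalence", None))
    elif kind == "categorical":
        probs = d.pop("probs", None)
        spec = CovariateSpec(name, "categorical",
                             probs=tuple(probs) if probs else None)
    elif kind == "continuous":
        spec = CovariateSpec(name, "continuous", dist=d.pop("dist", "norm"),
                             params=tuple(d.pop("params", (0.0, 1.0))))
    else:
        raise ValidationError(f"{name}: unknown covariate kind {kind!r}")
    if d:
        raise ValidationError(f"{name}: unexpected covariate keys {sorted(d)}")
    return spec, coding


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    cov_entries = d.pop("covariates", None)
    if not cov_entries:
        raise ValidationError("config needs a non-empty 'covariates' list")
    covariates, coding = [], {}
    for entry in cov_entries:
        spec, how = _covariate_from_dict(entry)
        covariates.append(spec)
        if how is not None:
            coding[spec.name] = how
    if "log_odds_ratios" in d:
        beta = {k: float(v) for k, v in d.pop("log_odds_ratios").items()}
    elif "odds_ratios" in d:
        beta = {k: float(np.log(v)) for k, v in d.pop("odds_ratios").items()}
    else:
        raise ValidationError("config needs 'odds_ratios' or 'log_odds_ratios'")
    fit = d.pop("fit", {}) or {}
    joint = d.pop("joint", None)
    if joint is not None:
        joint = pd.DataFrame(joint)
    try:
        cfg = ScenarioConfig(
            name=str(d.pop("name", "scenario")),
            covariates=covariates,
            beta=beta,
            target_prevalence=float(d.pop("prevalence")),
            coding=coding,
            interactions=[tuple(t) for t in d.pop("interactions", [])],
            joint=joint,
            population_size=int(d.pop("population_size", 100_000)),
            gamma=float(d.pop("gamma", 0.05)),
            tau=float(d.pop("tau", 0.005)),
            replicates=int(d.pop("replicates", 10_000)),
            fit_covariates=fit.get("covariates"),
            fit_coding=fit.get("coding"),
            fit_interactions=(None if "interactions" not in fit
                              else [tuple(t) for t in fit["interactions"]]),
            methods=tuple(d.pop("methods", ("present", "sato", "miettinen"))),
            notes=str(d.pop("notes", "")),
        )
    except KeyError as exc:
        raise ValidationError(f"config missing required key {exc}") from exc
    if d:
        raise ValidationError(f"unexpected config keys {sorted(d)}")
    return cfg


def read_scenario_config(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return scenario_from_dict(data)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report_to_dict(report: StudyReport) -> dict:
    return {
        "scenario": report.scenario,
        "replicates": report.replicates,
        "seed": report.seed,
        "notes": report.notes,
        "cells": _jsonable(report.table.to_dict(orient="records")),
    }


def write_report(report: StudyReport, path, fmt: str = "csv") -> None:
    """Write a study report: table-layout CSV (+ JSON sidecar) or JSON."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=1))
        return
    if fmt != "csv":
        raise ValidationError("format must be 'csv' or 'json'")
    report.to_wide(decimals=4).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(report_to_dict(report), indent=1))


def fit_to_dict(fit: CaseBaseFit, effects: dict | None = None) -> dict:
    """JSON-ready summary of a case-base fit (plus optional effect tables)."""
    out = {
        "columns": fit.columns,
        "alpha_star": fit.alpha_star,
        "alpha_hat": fit.alpha_hat,
        "beta": fit.beta_hat,
        "covariance": fit.logistic.covariance,
        "converged": fit.logistic.converged,
        "counts": {"n_rows": fit.n_rows, "n_D": fit.rho.n_D,
                   "n1": fit.rho.n1, "n11": fit.rho.n11},
        "rho": {"estimate": fit.rho.rho_hat, "var": fit.rho.var_rho,
                "var_log": fit.rho.var_log_rho},
        "gamma": {"estimate": fit.rho.gamma_hat, "var": fit.rho.var_gamma},
    }
    if effects:
        out["effects"] = {
            name: [dataclasses.asdict(e) for e in table]
            for name, table in effects.items()
        }
    return _jsonable(out)


@dataclasses.dataclass
class RunManifest:
    """Provenance record emitted next to every CLI output."""

    command: str
    arguments: dict
    seed: int | None
    config_hash: str | None
    package_version: str
    created: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    warnings: list = dataclasses.field(default_factory=list)

    @staticmethod
    def hash_file(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, out_path) -> Path:
        p = Path(str(out_path) + ".manifest.json")
        p.write_text(json.dumps(_jsonable(dataclasses.asdict(self)), indent=1))
        return p
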