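"""Comparison estimators for relative risk in case-base studies.

* :func:`sato_rr` — the maximum-likelihood RR estimator for one binary
  exposure, written in closed form. It is the algebraic specialization of
  the general intercept-corrected logistic estimator to a saturated
  single-binary-covariate model and agrees with it to machine precision.
* :func:`miettinen_rr` — the crude case-base RR: exposure odds among all
  recruited diseased divided by exposure odds in the base sample. The
  shipped variance is a documented reconstruction (sum of reciprocal
  counts of the four cells entering the point estimate).
* :func:`duplication_rr` — the data-duplication trick for estimating RRs
  with logistic software: diseased subjects recruited in the base sample
  are duplicated and the copies relabeled non-diseased, then a logistic
  model is fitted to the expanded data and its coefficients read as log
  RRs. Unbiased for a single binary exposure, but with larger variance
  than the model-based estimator, and biased for multi-level exposures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import build_matrix
from .errors import NotEstimableError, ValidationError
from .estimator import EffectEstimate, _fit_logistic_matrix, _wald

__all__ = [
    "BinaryCaseBaseTable",
    "sato_rr",
    "miettinen_rr",
    "duplication_rr",
    "binary_table_from_dataset",
    "dataset_from_binary_table",
]


@dataclass(frozen=True)
class BinaryCaseBaseTable:
    """Sufficient counts for a single-binary-exposure case-base analysis.

    ``diseased_*`` count ALL distinct recruited diseased subjects by
    exposure; ``base_*`` count base-sample members by exposure regardless
    of disease; ``diseased_in_base_*`` count their overlap.
    """

    diseased_exposed: int
    diseased_unexposed: int
    base_exposed: int
    base_unexposed: int
    diseased_in_base_exposed: int
    diseased_in_base_unexposed: int

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if (self.diseased_in_base_exposed > min(self.diseased_exposed,
                                                self.base_exposed)
                or self.diseased_in_base_unexposed > min(self.diseased_unexposed,
                                                         self.base_unexposed)):
            raise ValidationError(
                "overlap counts cannot exceed the diseased or base counts")

    @property
    def nondiseased_exposed(self) -> int:
        """Non-diseased recruits (base members only) with the exposure."""
        return self.base_exposed - self.diseased_in_base_exposed

    @property
    def nondiseased_unexposed(self) -> int:
        return self.base_unexposed - self.diseased_in_base_unexposed

    @property
    def n_D(self) -> int:
        return self.diseased_exposed + self.diseased_unexposed

    @property
    def n1(self) -> int:
        return self.diseased_in_base_exposed + self.diseased_in_base_unexposed


def sato_rr(table: BinaryCaseBaseTable, level: float = 0.95) -> EffectEstimate:
    """Sato's RR estimate and log-scale variance for one binary exposure.

    Closed-form specialization of the general method: the saturated sample
    logistic fit has exp(alpha*) = a0/b0 and exp(alpha* + beta) = a1/b1
    (a = recruited diseased, b = non-diseased recruits), the intercept is
    corrected by rho_hat = n1/n_D, and the delta-method variance collapses
    to binomial pieces per exposure arm plus the shared log-rho term.
    """
    a1, a0 = table.diseased_exposed, table.diseased_unexposed
    b1, b0 = table.nondiseased_exposed, table.nondiseased_unexposed
    if min(a1, a0, b1, b0) == 0:
        raise ValidationError(
            "all four cells (diseased and non-diseased recruits by exposure) "
            "must be positive")
    if table.n1 == 0:
        raise NotEstimableError("n1 = 0: rho and hence the RR are not estimable")
    rho = table.n1 / table.n_D
    var_log_rho = (1.0 - rho) / (table.n_D * rho)
    p1 = expit(np.log(a1 / b1) + np.log(rho))
    p0 = expit(np.log(a0 / b0) + np.log(rho))
    log_rr = np.log(p1) - np.log(p0)
    c = (1.0 - p1) - (1.0 - p0)
    var = ((1.0 - p1) ** 2 * (1.0 / a1 + 1.0 / b1)
           + (1.0 - p0) ** 2 * (1.0 / a0 + 1.0 / b0)
           + c * c * var_log_rho)
    return _wald("RR", log_rr, var, level, np.exp)


def miettinen_rr(table: BinaryCaseBaseTable, level: float = 0.95,
                 variance: str = "overlap") -> EffectEstimate:
    """Miettinen's crude case-base RR estimate.

    The point estimate is the exposure odds among recruited diseased over
    the exposure odds in the base sample; it never uses the overlap counts.
    The variance is a reconstruction (the original 1982 algebra is not
    reproduced here): ``variance="overlap"`` (default) is the delta-method
    variance acknowledging that the diseased base members appear in both
    the numerator and the denominator counts,

        1/a1 + 1/a0 + 1/B1 + 1/B0 - 2 o1/(a1 B1) - 2 o0/(a0 B0),

    with o the diseased-in-base overlap per arm; ``variance="reciprocal"``
    drops the covariance terms (conservative); ``variance="sato"`` borrows
    Sato's model-based variance.
    """
    a1, a0 = table.diseased_exposed, table.diseased_unexposed
    B1, B0 = table.base_exposed, table.base_unexposed
    if min(a1, a0, B1, B0) == 0:
        raise ValidationError("all four point-estimate cells must be positive")
    log_rr = np.log((a1 / a0) / (B1 / B0))
    if variance == "overlap":
        o1, o0 = table.diseased_in_base_exposed, table.diseased_in_base_unexposed
        var = (1.0 / a1 + 1.0 / a0 + 1.0 / B1 + 1.0 / B0
               - 2.0 * o1 / (a1 * B1) - 2.0 * o0 / (a0 * B0))
    elif variance == "reciprocal":
        var = 1.0 / a1 + 1.0 / a0 + 1.0 / B1 + 1.0 / B0
    elif variance == "sato":
        var = sato_rr(table).se_transformed ** 2
    else:
        raise ValidationError("variance must be 'overlap', 'reciprocal' or 'sato'")
    return _wald("RR", log_rr, var, level, np.exp)


def duplication_rr(dataset: pd.DataFrame,
                   terms: Sequence[str]) -> pd.DataFrame:
    """Log RR estimates by the duplicate-and-relabel logistic trick.

    Diseased subjects recruited in the base sample are duplicated, the
    copies are relabeled non-diseased, and a logistic regression of disease
    on ``terms`` is fitted to the expanded dataset; its coefficients are
    returned as log RR estimates with their naive Wald standard errors.
    """
    dup_mask = (dataset["disease"] == 1) & (dataset["in_base_sample"] == 1)
    if int(dup_mask.sum()) == 0:
        raise NotEstimableError(
            "n1 = 0: no diseased base-sample subjects to duplicate")
    copies = dataset.loc[dup_mask].copy()
    copies["disease"] = 0
    expanded = pd.concat([dataset, copies], ignore_index=True)
    X, enc = build_matrix(expanded, terms)
    fit = _fit_logistic_matrix(X, expanded["disease"].to_numpy(dtype=float),
                               columns=enc.columns)
    se = np.sqrt(np.diag(fit.covariance)[1:])
    z = 1.959963984540054
    return pd.DataFrame({
        "log_rr": fit.beta,
        "se": se,
        "ci_low": fit.beta - z * se,
        "ci_high": fit.beta + z * se,
    }, index=pd.Index(fit.columns, name="term"))


def binary_table_from_dataset(dataset: pd.DataFrame,
                              exposure: str) -> BinaryCaseBaseTable:
    """Collapse a single-binary-exposure dataset into its sufficient counts."""
    x = dataset[exposure].to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError(f"{exposure!r} must be a 0/1 exposure")
    d = dataset["disease"].to_numpy() == 1
    b = dataset["in_base_sample"].to_numpy() == 1
    e = x == 1.0
    return BinaryCaseBaseTable(
        diseased_exposed=int((d & e).sum()),
        diseased_unexposed=int((d & ~e).sum()),
        base_exposed=int((b & e).sum()),
        base_unexposed=int((b & ~e).sum()),
        diseased_in_base_exposed=int((d & b & e).sum()),
        diseased_in_base_unexposed=int((d & b & ~e).sum()),
    )


def dataset_from_binary_table(table: BinaryCaseBaseTable,
                              exposure: str = "x") -> pd.DataFrame:
    """Expand the sufficient counts back into a row-level dataset.

    Diseased base members get in_base_sample = 1; the remaining diseased
    recruits are assigned to the case sample (the case/base overlap split
    among them only affects the nuisance gamma, not risks or RRs).
    """
    rows = []

    def add(n, x, disease, case, base):
        rows.extend([(x, disease, case, base)] * int(n))

    for e, a, o, b in [(1, table.diseased_exposed, table.diseased_in_base_exposed,
                        table.nondiseased_exposed),
                       (0, table.diseased_unexposed, table.diseased_in_base_unexposed,
                        table.nondiseased_unexposed)]:
        add(o, e, 1, 0, 1)           # diseased, in base
        add(a - o, e, 1, 1, 0)       # diseased, case sample only
        add(b, e, 0, 0, 1)           # non-diseased base members
    out = pd.DataFrame(rows, columns=[exposure, "disease", "in_case_sample",
                                      "in_base_sample"])
    out.insert(0, "subject_id", np.arange(len(out)))
    return out
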