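"""Synthetic populations and case-base sampling.

A case-base study recruits two overlapping samples from the same study
population: a *case sample*, drawn with probability ``gamma`` among the
diseased only, and a *base sample*, drawn with probability ``tau`` from
everyone regardless of disease status. The two draws are independent, and a
subject selected by both schemes appears once in the dataset carrying both
membership flags — the analysis operates on distinct recruited subjects.

The key design quantity is rho = tau / (gamma + tau − gamma*tau), the
probability that a recruited diseased subject is in the base sample; its
empirical counterpart n1 / n_D later corrects the logistic intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySampleError, ValidationError
from .population import PopulationModel

__all__ = [
    "SamplingDesign",
    "SamplingCounts",
    "simulate_population",
    "draw_case_base_sample",
    "tabulate_counts",
    "validate_dataset",
]

FLAG_COLUMNS = ["disease", "in_case_sample", "in_base_sample"]


@dataclass(frozen=True)
class SamplingDesign:
    """Case-base sampling design.

    gamma is the case-sampling probability (among diseased subjects), tau
    the base-sampling probability (among all subjects).
    """

    population_size: int
    gamma: float
    tau: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValidationError("population_size must be >= 1")
        for name in ("gamma", "tau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.gamma == 0.0 and self.tau == 0.0:
            raise ValidationError("gamma and tau cannot both be zero")

    @property
    def rho(self) -> float:
        """P(in base sample | diseased and recruited)."""
        g, t = self.gamma, self.tau
        return t / (g + t - g * t)


@dataclass(frozen=True)
class SamplingCounts:
    """Counts of distinct diseased recruits driving the rho/gamma estimates."""

    n_D: int   # distinct diseased recruited (case sample ∪ base sample)
    n1: int    # diseased recruited in the base sample
    n11: int   # diseased recruited in both samples
    crosstab: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n11 <= self.n1 <= self.n_D:
            raise ValidationError(
                f"counts must satisfy 0 <= n11 <= n1 <= n_D, got "
                f"n11={self.n11}, n1={self.n1}, n_D={self.n_D}")


def _rng_streams(seed, n: int) -> list[np.random.Generator]:
    """Split one master seed into independent per-stage generators."""
    if isinstance(seed, np.random.SeedSequence):
        children = seed.spawn(n)
    elif isinstance(seed, np.random.Generator):
        # derive child streams deterministically from the generator
        children = np.random.SeedSequence(seed.integers(2**63)).spawn(n)
    else:
        children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_population(model: PopulationModel, n: int,
                        seed=None) -> pd.DataFrame:
    """Simulate a study population of n subjects.

    Covariates are drawn i.i.d. from the design's joint distribution and
    disease status is Bernoulli with the model's logistic risk. Separate
    random streams are used for covariates and disease so each stage is
    reproducible in isolation.
    """
    if n < 1:
        raise ValidationError("population size must be >= 1")
    cov_rng, dis_rng = _rng_streams(seed, 2)
    pop = model.design.sample(n, cov_rng)
    risk = model.risk(pop)
    pop["disease"] = dis_rng.binomial(1, risk)
    return pop


def draw_case_base_sample(population: pd.DataFrame,
                          design: SamplingDesign,
                          seed=None) -> pd.DataFrame:
    """Draw one case-base sample from a simulated population.

    Case sampling (probability gamma) applies to diseased subjects only;
    base sampling (probability tau) applies to everyone, independently.
    Returns the distinct recruited subjects with both membership flags and a
    ``subject_id`` column (the population row index).

    Raises
    ------
    EmptySampleError
        If no subject at all is recruited.
    """
    if len(population) == 0:
        raise ValidationError("population is empty")
    if "disease" not in population.columns:
        raise ValidationError("population must have a 'disease' column")
    if seed is None:
        seed = design.seed
    case_rng, base_rng = _rng_streams(seed, 2)
    n = len(population)
    disease = population["disease"].to_numpy()
    in_case = np.zeros(n, dtype=np.int64)
    diseased_idx = np.flatnonzero(disease == 1)
    in_case[diseased_idx] = case_rng.binomial(1, design.gamma, size=diseased_idx.size)
    in_base = base_rng.binomial(1, design.tau, size=n)
    recruited = (in_case + in_base) >= 1
    if not recruited.any():
        raise EmptySampleError(
            f"no subjects recruited (gamma={design.gamma}, tau={design.tau}, "
            f"N={n})")
    out = population.loc[recruited].copy()
    out.insert(0, "subject_id", np.flatnonzero(recruited))
    out["in_case_sample"] = in_case[recruited]
    out["in_base_sample"] = in_base[recruited]
    return out.reset_index(drop=True)


def validate_dataset(dataset: pd.DataFrame) -> None:
    """Check the case-base dataset invariants, raising ValidationError."""
    missing = [c for c in FLAG_COLUMNS if c not in dataset.columns]
    if missing:
        raise ValidationError(f"dataset missing required columns {missing}")
    for col in FLAG_COLUMNS:
        vals = dataset[col]
        if not np.isin(vals, (0, 1)).all():
            bad = dataset.index[~np.isin(vals, (0, 1))].tolist()[:5]
            raise ValidationError(f"column {col!r} must be 0/1; bad rows {bad}")
    bad = dataset.index[(dataset["in_case_sample"] == 1)
                        & (dataset["disease"] == 0)].tolist()
    if bad:
        raise ValidationError(
            f"rows {bad[:10]} are in the case sample but not diseased")
    bad = dataset.index[(dataset["in_case_sample"] == 0)
                        & (dataset["in_base_sample"] == 0)].tolist()
    if bad:
        raise ValidationError(
            f"rows {bad[:10]} are in neither sample; every row must be recruited")
    if "subject_id" in dataset.columns and dataset["subject_id"].duplicated().any():
        dup = dataset.loc[dataset["subject_id"].duplicated(), "subject_id"]
        raise ValidationError(
            f"duplicate subject_id values {sorted(set(dup))[:10]}; the dataset "
            "must hold distinct subjects with overlap recorded in the flags")


def tabulate_counts(dataset: pd.DataFrame) -> SamplingCounts:
    """Tabulate n_D, n1, n11 and the disease-by-membership cross table."""
    validate_dataset(dataset)
    disease = dataset["disease"].to_numpy()
    in_case = dataset["in_case_sample"].to_numpy()
    in_base = dataset["in_base_sample"].to_numpy()
    n_D = int((disease == 1).sum())
    n1 = int(((disease == 1) & (in_base == 1)).sum())
    n11 = int(((disease == 1) & (in_base == 1) & (in_case == 1)).sum())
    crosstab = (dataset.groupby(FLAG_COLUMNS).size().rename("count")
                .reset_index())
    return SamplingCounts(n_D=n_D, n1=n1, n11=n11, crosstab=crosstab)
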