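"""Covariate specifications and design-matrix encoding.

A :class:`CovariateSpec` describes the marginal distribution of one exposure
or confounder (binary, categorical with a reference level, or continuous).
A :class:`Design` maps raw covariate values to model columns: binary and
continuous covariates contribute one column each, categorical covariates are
either dummy-coded against level 0 or entered as a single integer score, and
optional pairwise interactions contribute product columns.

The design also knows the joint distribution of the covariates — by default
the product of the marginals, optionally an explicit joint profile table for
dependent covariates — which is what the baseline-odds solver integrates
over and what the population simulator draws from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

#: quadrature size for normal covariates (Gauss-Hermite)
_GH_POINTS = 80
#: Monte-Carlo draws used to approximate expectations for non-normal
#: continuous covariates, with a fixed internal seed
_MC_SUPPORT = 1_000_000
_MC_SEED = 987654321


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of a single covariate.

    Parameters
    ----------
    name : str
        Column name.
    kind : {"binary", "categorical", "continuous"}
    prevalence : float, optional
        P(X = 1) for a binary covariate; must lie in (0, 1).
    probs : sequence of float, optional
        Level probabilities for a categorical covariate (levels are the
        integers 0..k−1, level 0 is the reference); must sum to 1.
    dist : str
        scipy.stats distribution name for a continuous covariate.
    params : tuple of float
        Parameters passed to the scipy distribution (for ``"norm"``,
        ``(loc, scale)``).
    """

    name: str
    kind: str
    prevalence: float | None = None
    probs: tuple[float, ...] | None = None
    dist: str = "norm"
    params: tuple[float, ...] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValidationError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValidationError(
                    f"{self.name}: binary prevalence must lie in (0, 1)")
        elif self.kind == "categorical":
            if self.probs is None or len(self.probs) < 2:
                raise ValidationError(
                    f"{self.name}: categorical covariate needs >=2 level probabilities")
            p = np.asarray(self.probs, dtype=float)
            if np.any(p <= 0) or np.any(p >= 1) or abs(p.sum() - 1.0) > 1e-12:
                raise ValidationError(
                    f"{self.name}: level probabilities must lie in (0, 1) and sum to 1")
            object.__setattr__(self, "probs", tuple(float(x) for x in p))
        else:
            if not hasattr(scipy.stats, self.dist):
                raise ValidationError(f"{self.name}: unknown distribution {self.dist!r}")

    @property
    def n_levels(self) -> int:
        if self.kind == "binary":
            return 2
        if self.kind == "categorical":
            return len(self.probs)
        raise ValidationError(f"{self.name}: continuous covariate has no levels")

    @property
    def reference(self) -> float:
        """Reference value (0 for binary/categorical, 0.0 for continuous)."""
        return 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "binary":
            return rng.binomial(1, self.prevalence, size=n).astype(float)
        if self.kind == "categorical":
            return rng.choice(self.n_levels, p=self.probs, size=n).astype(float)
        if self.dist == "norm":
            loc, scale = self.params
            return rng.normal(loc, scale, size=n)
        frozen = getattr(scipy.stats, self.dist)(*self.params)
        return np.asarray(frozen.rvs(size=n, random_state=rng), dtype=float)

    def support(self) -> tuple[np.ndarray, np.ndarray]:
        """Values and weights for integrating over this covariate.

        Finite support for binary/categorical; Gauss-Hermite nodes for a
        normal covariate; fixed-seed Monte-Carlo draws otherwise.
        """
        if self.kind == "binary":
            return (np.array([0.0, 1.0]),
                    np.array([1.0 - self.prevalence, self.prevalence]))
        if self.kind == "categorical":
            return np.arange(self.n_levels, dtype=float), np.asarray(self.probs)
        if self.dist == "norm":
            loc, scale = self.params
            nodes, weights = np.polynomial.hermite.hermgauss(_GH_POINTS)
            return loc + scale * np.sqrt(2.0) * nodes, weights / np.sqrt(np.pi)
        frozen = getattr(scipy.stats, self.dist)(*self.params)
        draws = np.asarray(
            frozen.rvs(size=_MC_SUPPORT,
                       random_state=np.random.default_rng(_MC_SEED)),
            dtype=float)
        return draws, np.full(draws.shape, 1.0 / draws.size)


class Design:
    """Encoding of covariates into model columns.

    Parameters
    ----------
    covariates : sequence of CovariateSpec
    coding : dict, optional
        Per-covariate coding for categorical covariates: ``"dummy"``
        (default; indicator columns for levels 1..k−1 against reference
        level 0) or ``"score"`` (single column holding the level index,
        imposing a constant log odds ratio per adjacent level).
    interactions : sequence of (str, str), optional
        Product columns between two single-column covariates.
    joint : pandas.DataFrame, optional
        Explicit joint distribution for dependent covariates: one row per
        profile with the covariate columns plus a ``prob`` column summing
        to 1. Overrides the independence product.
    """

    def __init__(self,
                 covariates: Sequence[CovariateSpec],
                 coding: dict[str, str] | None = None,
                 interactions: Sequence[tuple[str, str]] = (),
                 joint: pd.DataFrame | None = None) -> None:
        names = [c.name for c in covariates]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate covariate names")
        self.covariates = list(covariates)
        self.coding = dict(coding or {})
        for name, how in self.coding.items():
            if name not in names:
                raise ValidationError(f"coding given for unknown covariate {name!r}")
            if how not in ("dummy", "score"):
                raise ValidationError(f"{name}: coding must be 'dummy' or 'score'")
        self.interactions = [tuple(t) for t in interactions]
        self.joint = None
        if joint is not None:
            joint = joint.copy()
            if "prob" not in joint.columns or set(names) - set(joint.columns):
                raise ValidationError(
                    "joint table needs the covariate columns and a 'prob' column")
            if abs(joint["prob"].sum() - 1.0) > 1e-12 or (joint["prob"] <= 0).any():
                raise ValidationError("joint probabilities must be positive and sum to 1")
            self.joint = joint
        self.columns = self._build_columns()

    def _coding_of(self, cov: CovariateSpec) -> str:
        return self.coding.get(cov.name, "dummy")

    def _build_columns(self) -> list[str]:
        cols: list[str] = []
        for cov in self.covariates:
            if cov.kind == "categorical" and self._coding_of(cov) == "dummy":
                cols.extend(f"{cov.name}[{lvl}]" for lvl in range(1, cov.n_levels))
            else:
                cols.append(cov.name)
        for a, b in self.interactions:
            for t in (a, b):
                if t not in cols:
                    raise ValidationError(
                        f"interaction term {t!r} is not a single model column")
            cols.append(f"{a}:{b}")
        return cols

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def encode(self, data: pd.DataFrame | dict) -> np.ndarray:
        """Encode raw covariate values into the model matrix (no intercept)."""
        if isinstance(data, dict):
            data = pd.DataFrame({k: np.atleast_1d(v) for k, v in data.items()})
        out: dict[str, np.ndarray] = {}
        for cov in self.covariates:
            if cov.name not in data.columns:
                raise ValidationError(f"missing covariate column {cov.name!r}")
            x = np.asarray(data[cov.name], dtype=float)
            if cov.kind in ("binary", "categorical"):
                levels = np.arange(cov.n_levels)
                if not np.isin(x, levels).all():
                    bad = sorted(set(x) - set(levels.astype(float)))
                    raise ValidationError(
                        f"{cov.name}: values {bad} outside levels 0..{cov.n_levels - 1}")
            if cov.kind == "categorical" and self._coding_of(cov) == "dummy":
                for lvl in range(1, cov.n_levels):
                    out[f"{cov.name}[{lvl}]"] = (x == lvl).astype(float)
            else:
                out[cov.name] = x
        for a, b in self.interactions:
            out[f"{a}:{b}"] = out[a] * out[b]
        return np.column_stack([out[c] for c in self.columns])

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw n i.i.d. covariate rows from the joint distribution."""
        if self.joint is not None:
            idx = rng.choice(len(self.joint), size=n, p=self.joint["prob"].to_numpy())
            rows = self.joint.drop(columns="prob").iloc[idx].reset_index(drop=True)
            return rows.astype(float)
        return pd.DataFrame(
            {cov.name: cov.sample(n, rng) for cov in self.covariates})

    def joint_support(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Joint profile table and weights used for expectations.

        For finite designs these are the exact joint probabilities; normal
        covariates contribute quadrature nodes, other continuous covariates
        Monte-Carlo draws.
        """
        if self.joint is not None:
            profiles = self.joint.drop(columns="prob").reset_index(drop=True)
            return profiles.astype(float), self.joint["prob"].to_numpy(dtype=float)
        values, weights = [], []
        for cov in self.covariates:
            v, w = cov.support()
            values.append(v)
            weights.append(w)
        size = int(np.prod([len(v) for v in values]))
        if size > 5_000_000:
            raise ValidationError(
                "joint covariate support too large to enumerate; "
                "use normal covariates (quadrature) or an explicit joint table")
        grids = np.meshgrid(*values, indexing="ij")
        wgrids = np.meshgrid(*weights, indexing="ij")
        profiles = pd.DataFrame(
            {cov.name: g.ravel() for cov, g in zip(self.covariates, grids)})
        prob = np.ones(size)
        for w in wgrids:
            prob = prob * w.ravel()
        return profiles, prob

    def finite_profiles(self) -> tuple[pd.DataFrame, np.ndarray] | None:
        """Exact joint support, or None if any covariate is continuous."""
        if self.joint is None and any(c.kind == "continuous" for c in self.covariates):
            return None
        return self.joint_support()

    def reference_profile(self) -> pd.DataFrame:
        """Single-row frame with every covariate at its reference value."""
        return pd.DataFrame({c.name: [c.reference] for c in self.covariates})


def profile_label(row: pd.Series | dict, covariates: Sequence[CovariateSpec]) -> str:
    """Compact label for a discrete profile, e.g. '10' for (x1=1, x2=0)."""
    parts = []
    for cov in covariates:
        v = float(row[cov.name])
        parts.append(str(int(v)) if float(v).is_integer() else f"{v:g}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# term-based model matrices for fitting observed datasets
# ---------------------------------------------------------------------------

@dataclass
class TermEncoder:
    """Remembers how dataset columns were expanded into model columns so the
    same encoding can be applied to new profiles (e.g. for risk queries)."""

    terms: list[str]
    columns: list[str] = field(default_factory=list)
    levels: dict[str, list[float]] = field(default_factory=dict)

    def encode(self, data: pd.DataFrame | dict, fit: bool = False) -> np.ndarray:
        if isinstance(data, dict):
            data = pd.DataFrame({k: np.atleast_1d(v) for k, v in data.items()})
        out: dict[str, np.ndarray] = {}
        columns: list[str] = []

        def base(term: str) -> np.ndarray:
            if term not in data.columns:
                raise ValidationError(f"model term {term!r} not in dataset columns")
            return np.asarray(data[term], dtype=float)

        for term in self.terms:
            if term.startswith("C(") and term.endswith(")"):
                name = term[2:-1]
                x = base(name)
                if fit:
                    self.levels[name] = sorted(set(x.tolist()))
                levels = self.levels.get(name)
                if levels is None:
                    raise ValidationError(f"categorical term {term!r} not fitted yet")
                unknown = sorted(set(x.tolist()) - set(levels))
                if unknown:
                    raise ValidationError(f"{name}: unknown categories {unknown}")
                for lvl in levels[1:]:
                    col = f"{name}[{lvl:g}]"
                    out[col] = (x == lvl).astype(float)
                    columns.append(col)
            elif ":" in term:
                a, b = term.split(":", 1)
                out[term] = base(a) * base(b)
                columns.append(term)
            else:
                out[term] = base(term)
                columns.append(term)
        if fit:
            self.columns = columns
        return np.column_stack([out[c] for c in columns]) if columns else \
            np.empty((len(data), 0))


def build_matrix(data: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, TermEncoder]:
    """Build a model matrix (no intercept) from term strings.

    Terms are column names, ``"C(col)"`` for dummy-coded categoricals
    (reference = smallest observed level), or ``"a:b"`` for products.
    """
    enc = TermEncoder(list(terms))
    X = enc.encode(data, fit=True)
    return X, enc
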