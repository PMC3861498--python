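"""Replicate-batched grouped logistic fitting for Monte-Carlo studies.

With discrete covariates the logistic likelihood depends on the data only
through the per-profile (diseased, recruited) counts, so thousands of
simulation replicates can be fitted at once: one Newton iteration solves a
small p x p system per replicate, vectorized over replicates. Replicates
with singular information (empty or separated cells) are flagged rather
than fitted.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_SEPARATION_BOUND = 30.0
_MAX_STEP = 10.0


def batched_logistic(X: np.ndarray, y: np.ndarray, m: np.ndarray,
                     tol: float = 1e-10, max_iter: int = 80
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit grouped logistic models, one per replicate.

    Parameters
    ----------
    X : (P, p) model matrix shared by all replicates (intercept included).
    y : (R, P) successes (diseased recruits) per profile.
    m : (R, P) totals (all recruits) per profile.

    Returns
    -------
    beta : (R, p) maximum-likelihood estimates.
    cov : (R, p, p) inverse information at the optimum.
    ok : (R,) True where the fit converged with finite, non-separated
        coefficients and invertible information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    R, P = y.shape
    p = X.shape[1]
    beta = np.zeros((R, p))
    ok = np.ones(R, dtype=bool)

    def hessian(b: np.ndarray) -> np.ndarray:
        mu = expit(b @ X.T)
        w = m * mu * (1.0 - mu)
        return np.einsum("rk,ki,kj->rij", w, X, X)

    converged = np.zeros(R, dtype=bool)
    for _ in range(max_iter):
        eta = beta @ X.T
        mu = expit(eta)
        grad = (y - m * mu) @ X
        H = hessian(beta)
        sign, _ = np.linalg.slogdet(H)
        bad = (sign <= 0) | ~np.isfinite(sign)
        if bad.any():
            ok &= ~bad
            H[bad] = np.eye(p)
            grad[bad] = 0.0
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # trust-region style damping; harmless for well-behaved counts
        norms = np.abs(step).max(axis=1)
        big = norms > _MAX_STEP
        if big.any():
            step[big] *= (_MAX_STEP / norms[big])[:, None]
        beta = beta + step
        converged = np.abs(step).max(axis=1) < tol
        if converged[ok].all():
            break

    ok &= converged
    ok &= np.isfinite(beta).all(axis=1)
    with np.errstate(invalid="ignore"):
        ok &= np.abs(beta[:, 1:]).max(axis=1, initial=0.0) <= _SEPARATION_BOUND
    H = hessian(beta)
    sign, _ = np.linalg.slogdet(H)
    bad = (sign <= 0) | ~np.isfinite(sign)
    ok &= ~bad
    H[bad] = np.eye(p)
    cov = np.linalg.inv(H)
    return beta, cov, ok


def sample_profile_counts(rng: np.random.Generator, replicates: int,
                          population_size: int, probs: np.ndarray,
                          risks: np.ndarray, gamma: float, tau: float
                          ) -> dict[str, np.ndarray]:
    """Simulate case-base recruitment as per-profile sufficient counts.

    Equivalent in distribution to simulating the population row by row and
    applying independent Bernoulli(gamma) case sampling among the diseased
    and Bernoulli(tau) base sampling overall, then counting per covariate
    profile. Returns arrays of shape (replicates, n_profiles):

    ``diseased``  distinct diseased recruits,
    ``in_base``   diseased recruits who are base members (n1 per profile),
    ``overlap``   diseased in both samples (n11 per profile),
    ``nondiseased`` non-diseased recruits (base members only).
    """
    counts = rng.multinomial(population_size, probs, size=replicates)
    d = rng.binomial(counts, risks)
    n_case = rng.binomial(d, gamma)
    n_both = rng.binomial(n_case, tau)
    n_base_only = rng.binomial(d - n_case, tau)
    return {
        "diseased": n_case + n_base_only,
        "in_base": n_both + n_base_only,
        "overlap": n_both,
        "nondiseased": rng.binomial(counts - d, tau),
    }
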