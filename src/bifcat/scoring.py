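"""Multidimensional MAP scoring with posterior-information standard errors.

The latent-trait posterior combines the pattern likelihood with a fixed
MVN(0, I) prior — matching the orthogonality of general and group factors
in the bifactor model.  The MAP estimate is the posterior mode; standard
errors come from the inverse of the posterior information matrix

    J(theta) = I_D + sum over administered items of item Fisher information,

so ``SE_d = sqrt([J^-1]_dd)``.  Expected (Fisher) information is the
default convention in both the SEs and the engine's determinant rule;
observed information is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import (
    InvalidInputError,
    ItemBank,
    _coerce_pattern,
    _pattern_terms,
)

__all__ = ["PosteriorState", "map_estimate", "posterior_information",
           "standard_errors", "ScoringError"]

THETA_BOUND = 6.0  # box constraint per dimension, matching quadrature support
GRAD_TOL = 1e-8
MAX_ITER = 200


class ScoringError(RuntimeError):
    """MAP optimizer failed to converge; carries diagnostics, never a silent value."""


@dataclass
class PosteriorState:
    """A respondent's evolving adaptive-testing state."""

    theta_hat: np.ndarray
    info: np.ndarray
    se: np.ndarray
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    theta_history: list[np.ndarray] = field(default_factory=list)


def map_estimate(pattern, bank: ItemBank, start: np.ndarray | None = None,
                 grad_tol: float = GRAD_TOL, max_iter: int = MAX_ITER) -> np.ndarray:
    """Maximum a posteriori trait estimate for a (partial) response pattern.

    Maximizes ``log L(theta) - ||theta||^2 / 2`` by damped Newton steps on
    the observed Hessian, falling back to Fisher scoring whenever the
    observed Hessian is not positive definite.  Dimensions with no
    administered information stay at the prior mode 0.
    """
    x = _coerce_pattern(pattern, bank)
    obs = np.flatnonzero(x >= 0)
    D = bank.D
    theta = np.zeros(D) if start is None else np.array(start, dtype=float)
    if theta.shape != (D,):
        raise InvalidInputError(f"start must have shape ({D},)")
    if obs.size == 0:
        return np.zeros(D)

    A = bank.loadings[obs]

    def neg_log_post(th):
        logp, u, c = _pattern_terms(x, th, bank, obs)
        f = 0.5 * th @ th - logp
        grad = th - A.T @ u
        return f, grad, u, c

    f, grad, u, c = neg_log_post(theta)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < grad_tol:
            return theta
        # observed Hessian of the negative log posterior
        H_obs = np.eye(D) + (A * (-c)[:, None]).T @ A
        step = None
        try:
            L = np.linalg.cholesky(H_obs)
            step = np.linalg.solve(L.T, np.linalg.solve(L, -grad))
        except np.linalg.LinAlgError:
            pass
        if step is None:
            # Fisher scoring direction: expected information is always PD here
            w = _fisher_weights(x, theta, bank, obs)
            H_exp = np.eye(D) + (A * w[:, None]).T @ A
            step = np.linalg.solve(H_exp, -grad)
        # backtracking line search on the negative log posterior
        t = 1.0
        for _ in range(40):
            cand = np.clip(theta + t * step, -THETA_BOUND, THETA_BOUND)
            f_new, grad_new, u_new, c_new = neg_log_post(cand)
            if f_new <= f + 1e-12:
                theta, f, grad, u, c = cand, f_new, grad_new, u_new, c_new
                break
            t *= 0.5
        else:
            raise ScoringError(
                f"line search stalled at theta={theta}, |grad|={np.max(np.abs(grad)):.2e}")
    if np.max(np.abs(grad)) < grad_tol:
        return theta
    raise ScoringError(
        f"MAP did not converge in {max_iter} iterations "
        f"(|grad|={np.max(np.abs(grad)):.2e}, theta={theta})")


def _fisher_weights(x, theta, bank: ItemBank, obs) -> np.ndarray:
    from .grm import _boundary_probs, _cat_probs_from_boundary, _grm_weight
    z = bank.loadings[obs] @ theta
    pstar = _boundary_probs(z, bank.padded_intercepts[obs])
    probs = _cat_probs_from_boundary(pstar)
    return _grm_weight(pstar, probs)


def posterior_information(theta_hat, pattern, bank: ItemBank,
                          observed: bool = False) -> np.ndarray:
    """Posterior information matrix at ``theta_hat``.

    Identity (the MVN(0, I) prior precision) plus the per-item information
    of every administered (non-missing) item, in the expected-information
    convention by default.  With ``observed=True`` the realized negative
    second derivatives replace the Fisher weights.
    """
    x = _coerce_pattern(pattern, bank)
    theta = np.asarray(theta_hat, dtype=float)
    obs = np.flatnonzero(x >= 0)
    D = bank.D
    if obs.size == 0:
        return np.eye(D)
    A = bank.loadings[obs]
    if observed:
        _, _, c = _pattern_terms(x, theta, bank, obs)
        w = -c
    else:
        w = _fisher_weights(x, theta, bank, obs)
    return np.eye(D) + (A * w[:, None]).T @ A


def standard_errors(info: np.ndarray) -> np.ndarray:
    """Per-dimension SEs: square roots of the diagonal of the inverse information."""
    info = np.asarray(info, dtype=float)
    try:
        L = np.linalg.cholesky(info)
    except np.linalg.LinAlgError as e:
        raise InvalidInputError("information matrix is not positive definite") from e
    inv = np.linalg.inv(info)
    return np.sqrt(np.diag(inv))
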