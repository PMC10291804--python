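"""Independent reference implementations used only as test oracles.

Nothing here imports from the package's estimation or selection code:
each oracle recomputes its quantity from first principles (grid search,
finite differences, brute-force enumeration, or a separately written 1-D
EM) so agreement is an actual cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm


# ---------------------------------------------------------------------
# direct logistic arithmetic for GRM category probabilities
# ---------------------------------------------------------------------

def grm_probs_direct(z: float, d: np.ndarray) -> np.ndarray:
    """Category probabilities by explicit telescoping of logistic terms."""
    bounds = [1.0] + [1.0 / (1.0 + np.exp(-(z + dk))) for dk in d] + [0.0]
    return np.array([bounds[k] - bounds[k + 1] for k in range(len(d) + 1)])


# ---------------------------------------------------------------------
# finite-difference expected Hessian (item Fisher information)
# ---------------------------------------------------------------------

def fisher_information_fd(a: np.ndarray, d: np.ndarray, theta: np.ndarray,
                          h: float = 1e-5) -> np.ndarray:
    """Negative expected Hessian of the item log-likelihood at theta.

    E over categories of -(d^2/dtheta^2) log P_k, each second derivative
    from central finite differences of the log category probability.
    """
    D = theta.size
    K = d.size + 1
    probs0 = grm_probs_direct(float(a @ theta), d)

    def logp(th, k):
        return np.log(grm_probs_direct(float(a @ th), d)[k])

    H = np.zeros((D, D))
    for k in range(K):
        Hk = np.zeros((D, D))
        for i in range(D):
            for j in range(D):
                tpp = theta.copy(); tpp[i] += h; tpp[j] += h
                tpm = theta.copy(); tpm[i] += h; tpm[j] -= h
                tmp = theta.copy(); tmp[i] -= h; tmp[j] += h
                tmm = theta.copy(); tmm[i] -= h; tmm[j] -= h
                Hk[i, j] = (logp(tpp, k) - logp(tpm, k)
                            - logp(tmp, k) + logp(tmm, k)) / (4 * h * h)
        H -= probs0[k] * Hk
    return H


# ---------------------------------------------------------------------
# 1-D grid search for the MAP posterior mode
# ---------------------------------------------------------------------

def map_grid_search_1d(responses: list[tuple[np.ndarray, int]],
                       step: float = 1e-4, bound: float = 6.0) -> float:
    """Posterior mode over a dense theta grid for general-only patterns.

    ``responses`` is a list of (intercepts, observed category) pairs for
    items with unit-free general slope folded into the intercept call;
    here each tuple is (a_general, intercepts, category).
    """
    grid = np.arange(-bound, bound + step, step)
    logpost = -0.5 * grid**2
    for a_gen, d, k in responses:
        pk = np.array([grm_probs_direct(a_gen * t, d)[k] for t in grid])
        logpost += np.log(np.maximum(pk, 1e-300))
    return float(grid[np.argmax(logpost)])


# ---------------------------------------------------------------------
# brute-force determinant-rule selection
# ---------------------------------------------------------------------

def select_by_full_determinant(info: np.ndarray, theta: np.ndarray, bank,
                               excluded: set[str]) -> str:
    """Argmax of det(info + item information) by direct determinant evaluation."""
    best_id, best_det = None, -np.inf
    for it in bank.items:
        if it.item_id in excluded:
            continue
        a = np.zeros(bank.D)
        a[0] = it.a_general
        if it.group_index > 0:
            a[it.group_index] = it.a_group
        z = float(a @ theta)
        probs = grm_probs_direct(z, it.intercepts)
        bounds = np.array([1.0] + list(expit(z + it.intercepts)) + [0.0])
        q = bounds * (1 - bounds)
        w = float(np.sum((q[:-1] - q[1:]) ** 2 / np.maximum(probs, 1e-300)))
        det = np.linalg.det(info + w * np.outer(a, a))
        if det > best_det:
            best_det, best_id = det, it.item_id
    return best_id


# ---------------------------------------------------------------------
# unidimensional graded-response EM (Bock-Aitkin, 1-D quadrature)
# ---------------------------------------------------------------------

def fit_unidimensional_grm(x: np.ndarray, max_cycles: int = 500,
                           tol: float = 1e-6, nq: int = 21):
    """Marginal ML for a 1-D GRM; returns (slopes, intercept lists, loglik).

    Written independently of the package estimator: per-item M-steps use
    numerically safeguarded direct parameterization with an ordering
    penalty-free reparameterization via sorted offsets.
    """
    n, I = x.shape
    K = np.array([int(x[x[:, i] >= 0, i].max()) + 1 for i in range(I)])
    q = np.linspace(-6, 6, nq)
    w = norm.pdf(q)
    w = w / w.sum()

    a = np.ones(I)
    d = []
    for i in range(I):
        col = x[x[:, i] >= 0, i]
        cum = np.array([(col >= k).mean() for k in range(1, K[i])])
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        di = np.log(cum / (1 - cum))
        di = np.minimum.accumulate(di) - 1e-3 * np.arange(K[i] - 1)
        d.append(di)

    def item_probs(i):
        # (K_i, nq) category probability table
        ps = expit(a[i] * q[None, :] + d[i][:, None])
        full = np.vstack([np.ones(nq), ps, np.zeros(nq)])
        return full[:-1] - full[1:]

    prev_ll = -np.inf
    ll = prev_ll
    for cycle in range(max_cycles):
        tables = [np.maximum(item_probs(i), 1e-10) for i in range(I)]
        logL = np.zeros((n, nq))
        for i in range(I):
            m = x[:, i] >= 0
            logL[m] += np.log(tables[i][x[m, i]])
        joint = logL + np.log(w)[None, :]
        mx = joint.max(axis=1, keepdims=True)
        lik = np.exp(joint - mx)
        person = lik.sum(axis=1)
        ll = float((np.log(person) + mx[:, 0]).sum())
        post = lik / person[:, None]

        max_change = 0.0
        for i in range(I):
            m = x[:, i] >= 0
            r = np.zeros((K[i], nq))
            for k in range(K[i]):
                r[k] = post[m & (x[:, i] == k)].sum(axis=0)

            def negq(p):
                ai = p[0]
                di = np.concatenate([[p[1]], p[1] - np.cumsum(np.exp(p[2:]))])
                ps = expit(ai * q[None, :] + di[:, None])
                full = np.vstack([np.ones(nq), ps, np.zeros(nq)])
                probs = np.maximum(full[:-1] - full[1:], 1e-10)
                return -np.sum(r * np.log(probs))

            p0 = np.concatenate([[a[i]], [d[i][0]],
                                 np.log(np.maximum(-np.diff(d[i]), 1e-6))])
            res = minimize(negq, p0, method="Nelder-Mead",
                           options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-10})
            p = res.x
            new_a = p[0]
            new_d = np.concatenate([[p[1]], p[1] - np.cumsum(np.exp(p[2:]))])
            max_change = max(max_change, abs(new_a - a[i]),
                             float(np.max(np.abs(new_d - d[i]))))
            a[i], d[i] = new_a, new_d

        if max_change < 1e-4 or abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    if a.sum() < 0:
        a = -a
    return a, d, ll
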