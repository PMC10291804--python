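"""Bifactor GRM calibration, local-dependence screening, and fit summaries.

Estimation is marginal maximum likelihood via Bock-Aitkin EM, exploiting
the bifactor dimension reduction: because each item loads on the general
factor and at most one group factor, the person likelihood factors as

    L_j = Int phi(t0) * Prod_general-only P_i(t0)
          * Prod_g [ Int phi(tg) Prod_{i in g} P_i(t0, tg) dtg ] dt0,

so only two-dimensional quadrature grids are ever needed regardless of
the number of group factors.  Missing responses are simply omitted from
the likelihood (full-information treatment, no imputation).

Local dependence is screened with Yen's Q3: residuals are the differences
between observed responses and the model-reproduced expected responses at
the person's full-pattern MAP estimate, and Q3 for a pair is the Pearson
correlation of the two residual columns.  Pairs above the threshold are
resolved by removing the member with the smaller prior-integrated item
information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .grm import (
    PROB_FLOOR,
    InvalidInputError,
    ItemBank,
    ItemParameters,
    _boundary_probs,
    _cat_probs_from_boundary,
    _grm_weight,
)
from .scoring import map_estimate

__all__ = [
    "EstimationSettings", "CalibrationResult", "fit_bifactor_grm",
    "q3_matrix", "screen_local_dependence", "LocalDependenceReport",
    "item_information_scalar", "srmsr",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EstimationSettings:
    """EM configuration.

    21 equally spaced quadrature points on [-6, 6] with renormalized
    normal-density weights per dimension; convergence when the largest
    absolute parameter change drops below ``param_tol`` or the marginal
    log-likelihood change drops below ``ll_tol``, capped at ``max_cycles``.
    """

    n_quadrature: int = 21
    theta_range: tuple[float, float] = (-6.0, 6.0)
    max_cycles: int = 500
    param_tol: float = 1e-4
    ll_tol: float = 1e-6
    on_unobserved_category: str = "collapse"  # or "error"


@dataclass
class CalibrationResult:
    bank: ItemBank
    log_likelihood_trajectory: np.ndarray
    converged: bool
    n_cycles: int
    category_maps: dict[str, np.ndarray] = field(default_factory=dict)


def _quadrature(settings: EstimationSettings) -> tuple[np.ndarray, np.ndarray]:
    q = np.linspace(*settings.theta_range, settings.n_quadrature)
    w = norm.pdf(q)
    return q, w / w.sum()


def _coerce_responses(responses, structure) -> tuple[np.ndarray, list[str]]:
    if isinstance(responses, pd.DataFrame):
        ids = list(responses.columns)
        x = responses.to_numpy()
    else:
        x = np.asarray(responses)
        ids = list(structure.keys())
        if x.ndim != 2 or x.shape[1] != len(ids):
            raise InvalidInputError(
                f"response matrix must be (n, {len(ids)}), got {x.shape}")
    if x.dtype.kind == "f":
        x = np.where(np.isnan(x), -1, x).astype(int)
    else:
        x = x.astype(int)
    missing_struct = [i for i in ids if i not in structure]
    if missing_struct:
        raise InvalidInputError(f"items without a structure entry: {missing_struct}")
    return x, ids


def _collapse_categories(x: np.ndarray, ids: list[str],
                         settings: EstimationSettings) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Remap each item's observed categories to contiguous 0..K'-1.

    Unobserved interior categories are collapsed into the adjacent lower
    observed category (a logged warning), or raised in strict mode.
    """
    maps: dict[str, np.ndarray] = {}
    out = x.copy()
    for i, iid in enumerate(ids):
        col = x[:, i]
        observed = np.unique(col[col >= 0])
        if observed.size < 2:
            raise InvalidInputError(
                f"item {iid!r}: needs >= 2 observed categories")
        if np.all(np.diff(observed) == 1) and observed[0] == 0:
            maps[iid] = observed
            continue
        if settings.on_unobserved_category == "error":
            raise InvalidInputError(
                f"item {iid!r}: unobserved categories {set(range(observed.max() + 1)) - set(observed)}")
        warnings.warn(
            f"item {iid!r}: collapsing to {observed.size} observed categories",
            stacklevel=3)
        remap = np.searchsorted(observed, col[col >= 0])
        out[col >= 0, i] = remap
        maps[iid] = observed
    return out, maps


# ---------------------------------------------------------------------
# per-item expected-complete-data log-likelihood (M-step objective)
# ---------------------------------------------------------------------


def _unpack_d(pvec_d: np.ndarray) -> np.ndarray:
    """(d1, tau_2..tau_{K-1}) -> strictly decreasing intercepts."""
    d1 = pvec_d[0]
    if pvec_d.size == 1:
        return np.array([d1])
    dec = np.cumsum(np.exp(pvec_d[1:]))
    return np.concatenate([[d1], d1 - dec])


def _pack_d(d: np.ndarray) -> np.ndarray:
    if d.size == 1:
        return np.array([d[0]])
    return np.concatenate([[d[0]], np.log(-np.diff(d))])


def _neg_q(pvec, r, t_gen, t_grp):
    """Negative expected complete-data log-likelihood and gradient for one item.

    ``r`` is the (K, Ngrid) expected count table from the E-step, ``t_gen``
    and ``t_grp`` the flattened grid coordinates (``t_grp`` None for a
    general-only item).
    """
    K = r.shape[0]
    if t_grp is None:
        a_gen, d_raw = pvec[0], pvec[1:]
        z = a_gen * t_gen
    else:
        a_gen, a_grp, d_raw = pvec[0], pvec[1], pvec[2:]
        z = a_gen * t_gen + a_grp * t_grp
    d = _unpack_d(d_raw)
    pstar = expit(z[:, None] + d[None, :])          # (Ngrid, K-1)
    probs = _cat_probs_from_boundary(pstar)          # (Ngrid, K)
    P = np.maximum(probs, PROB_FLOOR)
    rT = r.T                                         # (Ngrid, K)

    Q = np.sum(rT * np.log(P))

    q = pstar * (1.0 - pstar)
    zeros = np.zeros((z.size, 1))
    qfull = np.concatenate([zeros, q, zeros], axis=1)
    dPdz = -np.diff(qfull, axis=1)                   # (Ngrid, K)
    ratio = rT / P
    dQdz = np.sum(ratio * dPdz, axis=1)
    grad_d = np.sum(q * (ratio[:, 1:] - ratio[:, :-1]), axis=0)  # dQ/dd_m

    # chain rule through the monotone parameterization of d
    gd1 = grad_d.sum()
    if d_raw.size > 1:
        tail = np.cumsum(grad_d[::-1])[::-1]         # sum_{k >= m} dQ/dd_k
        gtau = -np.exp(d_raw[1:]) * tail[1:]
        gd = np.concatenate([[gd1], gtau])
    else:
        gd = np.array([gd1])

    if t_grp is None:
        grad = np.concatenate([[np.sum(dQdz * t_gen)], gd])
    else:
        grad = np.concatenate([[np.sum(dQdz * t_gen)],
                               [np.sum(dQdz * t_grp)], gd])
    return -Q, -grad


def _item_prob_table(a_gen, a_grp, d, q, group: bool) -> np.ndarray:
    """(K, Q, Q) table for a group item, (K, Q) for a general-only item."""
    if group:
        z = a_gen * q[:, None] + a_grp * q[None, :]
    else:
        z = a_gen * q
    pstar = _boundary_probs(z, d)
    probs = _cat_probs_from_boundary(pstar)
    return np.moveaxis(probs, -1, 0)


def fit_bifactor_grm(responses, structure: dict[str, int],
                     settings: EstimationSettings | None = None) -> CalibrationResult:
    """Full-information ML calibration of the bifactor GRM by EM.

    Parameters
    ----------
    responses:
        DataFrame (columns = item ids, NaN = missing) or integer array
        with -1 as the missing marker, columns ordered as ``structure``.
    structure:
        item_id -> group factor index (0 = loads on the general factor only).
    """
    settings = settings or EstimationSettings()
    x, ids = _coerce_responses(responses, structure)
    n = x.shape[0]
    obs_counts = (x >= 0).sum(axis=0)
    if np.any(obs_counts < 2):
        bad = [ids[i] for i in np.flatnonzero(obs_counts < 2)]
        raise InvalidInputError(f"items with < 2 observed responses: {bad}")
    x, category_maps = _collapse_categories(x, ids, settings)

    groups = np.array([structure[i] for i in ids], dtype=int)
    G = int(groups.max())
    q, wq = _quadrature(settings)
    logwq = np.log(wq)
    nq = q.size
    K_arr = np.array([int(x[x[:, i] >= 0, i].max()) + 1 for i in range(len(ids))])

    # ---- initialize: unit general slopes, cumulative-proportion intercepts
    a_gen = np.ones(len(ids))
    a_grp = np.where(groups > 0, 0.5, 0.0)
    d_list: list[np.ndarray] = []
    for i in range(len(ids)):
        col = x[x[:, i] >= 0, i]
        K = K_arr[i]
        cum = np.array([(col >= k).mean() for k in range(1, K)])
        d0 = np.clip(np.log(cum / (1 - cum + 1e-12) + 1e-12), -3.5, 3.5)
        d0 = np.minimum.accumulate(d0)  # enforce nonincreasing
        eps = 1e-2 * np.arange(K - 1)
        d_list.append(d0 - eps)

    gen_only = np.flatnonzero(groups == 0)
    group_members = {g: np.flatnonzero(groups == g) for g in range(1, G + 1)}
    t0_flat_2d = np.repeat(q, nq)
    tg_flat_2d = np.tile(q, nq)

    trajectory: list[float] = []
    converged = False
    cycle = 0
    prev_ll = -np.inf

    for cycle in range(1, settings.max_cycles + 1):
        # ---- E-step ------------------------------------------------------
        tables = [_item_prob_table(a_gen[i], a_grp[i], d_list[i], q,
                                   group=groups[i] > 0)
                  for i in range(len(ids))]

        logL0 = np.zeros((n, nq))
        for i in gen_only:
            m = x[:, i] >= 0
            logL0[m] += np.log(np.maximum(tables[i][x[m, i]], PROB_FLOOR))

        logLg_all = {}
        logLg_marg = np.zeros((n, nq))
        for g, members in group_members.items():
            logLg = np.zeros((n, nq, nq))
            for i in members:
                m = x[:, i] >= 0
                logLg[m] += np.log(np.maximum(tables[i][x[m, i]], PROB_FLOOR))
            marg = logsumexp(logLg + logwq[None, None, :], axis=2)
            logLg_all[g] = (logLg, marg)
            logLg_marg += marg

        logL = logL0 + logLg_marg                      # (n, nq)
        person_ll = logsumexp(logL + logwq[None, :], axis=1)
        ll = float(person_ll.sum())
        trajectory.append(ll)

        p0 = np.exp(logL + logwq[None, :] - person_ll[:, None])  # (n, nq)

        counts: list[np.ndarray] = [None] * len(ids)  # type: ignore[list-item]
        for i in gen_only:
            K = K_arr[i]
            r = np.zeros((K, nq))
            m = x[:, i] >= 0
            for k in range(K):
                sel = m & (x[:, i] == k)
                if sel.any():
                    r[k] = p0[sel].sum(axis=0)
            counts[i] = r
        for g, members in group_members.items():
            logLg, marg = logLg_all[g]
            pjoint = p0[:, :, None] * np.exp(
                logwq[None, None, :] + logLg - marg[:, :, None])
            for i in members:
                K = K_arr[i]
                r = np.zeros((K, nq, nq))
                m = x[:, i] >= 0
                for k in range(K):
                    sel = m & (x[:, i] == k)
                    if sel.any():
                        r[k] = pjoint[sel].sum(axis=0)
                counts[i] = r

        # ---- M-step ------------------------------------------------------
        max_change = 0.0
        for i in range(len(ids)):
            is_group = groups[i] > 0
            if is_group:
                x0 = np.concatenate([[a_gen[i]], [a_grp[i]], _pack_d(d_list[i])])
                r = counts[i].reshape(K_arr[i], -1)
                args = (r, t0_flat_2d, tg_flat_2d)
            else:
                x0 = np.concatenate([[a_gen[i]], _pack_d(d_list[i])])
                args = (counts[i], q, None)
            res = minimize(_neg_q, x0, args=args, jac=True, method="L-BFGS-B",
                           options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-8})
            p = res.x
            if is_group:
                new_a_gen, new_a_grp, new_d = p[0], p[1], _unpack_d(p[2:])
            else:
                new_a_gen, new_a_grp, new_d = p[0], 0.0, _unpack_d(p[1:])
            max_change = max(
                max_change,
                abs(new_a_gen - a_gen[i]), abs(new_a_grp - a_grp[i]),
                float(np.max(np.abs(new_d - d_list[i]))))
            a_gen[i], a_grp[i], d_list[i] = new_a_gen, new_a_grp, new_d

        if max_change < settings.param_tol or abs(ll - prev_ll) < settings.ll_tol:
            converged = True
            break
        prev_ll = ll

    # ---- orientation: reflect factors to a reproducible sign convention
    if a_gen.sum() < 0:
        a_gen = -a_gen
    for g, members in group_members.items():
        if a_grp[members].sum() < 0:
            a_grp[members] = -a_grp[members]

    items = []
    for i, iid in enumerate(ids):
        if a_gen[i] <= 0:
            raise CalibrationError(
                f"item {iid!r}: non-positive general slope {a_gen[i]:.4f} after "
                "orientation; data may not identify the general factor")
        items.append(ItemParameters(
            item_id=iid, group_index=int(groups[i]),
            a_general=float(a_gen[i]),
            a_group=float(a_grp[i]) if groups[i] > 0 else 0.0,
            intercepts=d_list[i]))
    bank = ItemBank(items=items, G=G)
    return CalibrationResult(
        bank=bank,
        log_likelihood_trajectory=np.array(trajectory),
        converged=converged,
        n_cycles=cycle,
        category_maps=category_maps,
    )


# ---------------------------------------------------------------------
# Yen's Q3 and screening
# ---------------------------------------------------------------------


def q3_matrix(responses, bank: ItemBank) -> pd.DataFrame:
    """Pairwise residual correlations (Yen's Q3) under the fitted model.

    Residuals are ``x_ji - E_i(theta_hat_j)`` with the full-pattern MAP
    estimate; Q3 for a pair is the Pearson correlation of the residual
    columns over persons with both items observed.  Pairs with fewer than
    3 jointly observed persons are NaN; the diagonal is NaN by convention.
    """
    if isinstance(responses, pd.DataFrame):
        x = responses[bank.item_ids].to_numpy()
    else:
        x = np.asarray(responses)
    if x.dtype.kind == "f":
        x = np.where(np.isnan(x), -1, x).astype(int)
    else:
        x = x.astype(int)
    n = x.shape[0]
    resid = np.full(x.shape, np.nan)
    theta = np.zeros(bank.D)
    for j in range(n):
        theta = map_estimate(x[j], bank, start=np.zeros(bank.D))
        z = bank.loadings @ theta
        pstar = _boundary_probs(z, bank.padded_intercepts)
        probs = _cat_probs_from_boundary(pstar)
        expected = probs @ np.arange(bank.max_categories)
        m = x[j] >= 0
        resid[j, m] = x[j, m] - expected[m]
    q3 = pd.DataFrame(resid, columns=bank.item_ids).corr(min_periods=3)
    np.fill_diagonal(q3.values, np.nan)
    return q3


@dataclass
class LocalDependenceReport:
    flagged_pairs: list[tuple[str, str, float]]  # descending Q3
    removed: list[str]
    threshold: float


def item_information_scalar(item: ItemParameters,
                            n_quadrature: int = 21,
                            theta_range: tuple[float, float] = (-6.0, 6.0)) -> float:
    """Prior-integrated trace of the item information matrix.

    The trace of ``w(z) a a^T`` is ``w(z) ||a||^2``; it is averaged over
    the standard-normal prior on the item's loaded dimensions (2-D grid
    for group items, 1-D for general-only), giving a global single-number
    summary of the item's information function for pair comparisons.
    """
    q = np.linspace(*theta_range, n_quadrature)
    w = norm.pdf(q)
    w = w / w.sum()
    norm2 = item.a_general**2 + item.a_group**2
    if item.group_index > 0:
        z = item.a_general * q[:, None] + item.a_group * q[None, :]
        weight = np.outer(w, w)
    else:
        z = item.a_general * q
        weight = w
    pstar = _boundary_probs(z, item.intercepts)
    fw = _grm_weight(pstar, _cat_probs_from_boundary(pstar))
    return float(np.sum(weight * fw) * norm2)


def screen_local_dependence(q3: pd.DataFrame, bank: ItemBank,
                            threshold: float = 0.20,
                            absolute: bool = False,
                            information: dict[str, float] | None = None,
                            ) -> LocalDependenceReport:
    """Flag item pairs with Q3 above the threshold and resolve them greedily.

    Pairs are processed in descending Q3 order; a pair both of whose
    members are still present loses its lower-information member (ties
    remove the later bank item).  Pairs already resolved by an earlier
    removal are skipped, so every flagged pair ends with at least one
    member removed.  ``information`` overrides the prior-integrated
    information computed from the bank (e.g., precomputed values).
    """
    ids = bank.item_ids
    if information is None:
        information = {it.item_id: item_information_scalar(it) for it in bank.items}
    vals = q3.loc[ids, ids].to_numpy()
    flagged = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = vals[i, j]
            if np.isnan(v):
                continue
            stat = abs(v) if absolute else v
            if stat > threshold:
                flagged.append((ids[i], ids[j], float(v)))
    flagged.sort(key=lambda t: (-(abs(t[2]) if absolute else t[2]), t[0], t[1]))
    removed: list[str] = []
    gone: set[str] = set()
    for a, b, _v in flagged:
        if a in gone or b in gone:
            continue
        ia, ib = information[a], information[b]
        if ia < ib:
            drop = a
        elif ib < ia:
            drop = b
        else:
            drop = b if ids.index(b) > ids.index(a) else a
        removed.append(drop)
        gone.add(drop)
    return LocalDependenceReport(flagged_pairs=flagged, removed=removed,
                                 threshold=threshold)


# ---------------------------------------------------------------------
# SRMSR
# ---------------------------------------------------------------------


def srmsr(responses, bank: ItemBank, n_quadrature: int = 21,
          theta_range: tuple[float, float] = (-6.0, 6.0)) -> float:
    """Standardized root mean square residual of inter-item correlations.

    Square root of the mean squared difference between observed
    (pairwise-complete Pearson) and model-implied inter-item correlations.
    Model moments integrate over the dimensions two items share: a 2-D
    grid for same-group pairs, the general dimension alone (with group
    factors integrated out) otherwise.
    """
    if isinstance(responses, pd.DataFrame):
        df = responses[bank.item_ids]
    else:
        arr = np.asarray(responses, dtype=float)
        arr = np.where(arr < 0, np.nan, arr)
        df = pd.DataFrame(arr, columns=bank.item_ids)
    r_obs = df.corr(min_periods=3).to_numpy()

    q = np.linspace(*theta_range, n_quadrature)
    w = norm.pdf(q)
    w = w / w.sum()
    nq = q.size
    I = bank.n_items
    kvec = np.arange(bank.max_categories)

    # conditional expected scores on the (t0, tg) grid, and t0-margins
    E_grid = np.zeros((I, nq, nq))
    E2_grid = np.zeros((I, nq, nq))
    for i, it in enumerate(bank.items):
        if it.group_index > 0:
            z = it.a_general * q[:, None] + it.a_group * q[None, :]
        else:
            z = np.broadcast_to(it.a_general * q[:, None], (nq, nq))
        pstar = _boundary_probs(z, bank.padded_intercepts[i])
        probs = _cat_probs_from_boundary(pstar)
        E_grid[i] = probs @ kvec
        E2_grid[i] = probs @ kvec**2
    Ebar = E_grid @ w                     # (I, nq): E[x | t0]
    m1 = Ebar @ w                         # E[x]
    m2 = (E2_grid @ w) @ w                # E[x^2]
    var = m2 - m1**2

    groups = bank.group_indices
    r_model = np.empty((I, I))
    # cross-group / general-only pairs: integrate the t0-margins
    cross = (Ebar * w[None, :]) @ Ebar.T  # E[x_i x_j] for independent-given-t0 pairs
    r_model[:] = (cross - np.outer(m1, m1)) / np.sqrt(np.outer(var, var))
    # same-group pairs share the group dimension too
    for g in range(1, bank.G + 1):
        members = np.flatnonzero(groups == g)
        for ii, i in enumerate(members):
            for jj in members[ii + 1:]:
                eij = float(np.sum(np.outer(w, w) * E_grid[i] * E_grid[jj]))
                r = (eij - m1[i] * m1[jj]) / np.sqrt(var[i] * var[jj])
                r_model[i, jj] = r_model[jj, i] = r

    iu = np.triu_indices(I, k=1)
    diff = r_obs[iu] - r_model[iu]
    diff = diff[~np.isnan(diff)]
    if diff.size == 0:
        raise InvalidInputError("no item pair with an observed correlation")
    return float(np.sqrt(np.mean(diff**2)))
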