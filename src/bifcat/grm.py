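"""Bifactor graded response model: probabilities, likelihoods, information.

The bifactor GRM links an ordinal item response ``x`` in ``{0, ..., K-1}``
to a latent trait vector ``theta`` of dimension ``D = G + 1`` (index 0 is
the general factor, indices 1..G the group factors).  Each item loads on
the general factor and on at most one group factor, so its linear score is

    z = a_general * theta[0] + a_group * theta[g]

and the boundary ("operating characteristic") probabilities are

    P*_k(theta) = logistic(z + d_k),   k = 1, ..., K-1,

with intercepts d_1 > d_2 > ... > d_{K-1} guaranteeing nonnegative
category probabilities P_k = P*_k - P*_{k+1} (P*_0 = 1, P*_K = 0).

Everything downstream (EM calibration, MAP scoring, determinant-rule item
selection) is built from the kernels in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemParameters",
    "ItemBank",
    "category_probabilities",
    "item_information",
    "pattern_log_likelihood",
    "expected_item_score",
    "intercepts_from_difficulties",
    "difficulties_from_intercepts",
    "PROB_FLOOR",
]

#: numerical floor applied to category probabilities inside logarithms and
#: denominators; prevents -inf log-likelihoods at extreme theta.
PROB_FLOOR = 1e-10

MISSING = -1  # integer missing-response marker used throughout


class InvalidInputError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of a single bifactor-GRM item (slope-intercept form).

    Parameters
    ----------
    item_id:
        Unique string label.
    group_index:
        Group factor the item loads on, in ``1..G``; ``0`` means the item
        loads on the general factor only.
    a_general:
        Discrimination on the general factor (logit units per trait SD);
        constrained positive to fix the reflection of the general factor.
    a_group:
        Discrimination on the item's group factor; 0 for general-only
        items, otherwise unconstrained in sign.
    intercepts:
        ``K-1`` strictly decreasing intercepts ``d_k``.
    """

    item_id: str
    group_index: int
    a_general: float
    a_group: float
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.intercepts, dtype=float)
        object.__setattr__(self, "intercepts", d)
        if d.ndim != 1 or d.size < 1:
            raise InvalidInputError(
                f"item {self.item_id!r}: needs >= 1 intercept (K >= 2)")
        if not np.all(np.isfinite(d)):
            raise InvalidInputError(f"item {self.item_id!r}: non-finite intercepts")
        if d.size > 1 and not np.all(np.diff(d) < 0):
            raise InvalidInputError(
                f"item {self.item_id!r}: intercepts must be strictly decreasing, got {d}")
        if not self.a_general > 0:
            raise InvalidInputError(
                f"item {self.item_id!r}: a_general must be positive (got {self.a_general})")
        if self.group_index < 0:
            raise InvalidInputError(f"item {self.item_id!r}: negative group_index")
        if self.group_index == 0 and self.a_group != 0.0:
            raise InvalidInputError(
                f"item {self.item_id!r}: general-only item must have a_group == 0")

    @property
    def n_categories(self) -> int:
        return self.intercepts.size + 1

    def loading_vector(self, D: int) -> np.ndarray:
        """Sparse loading vector of length ``D`` (nonzero at 0 and group_index)."""
        a = np.zeros(D)
        a[0] = self.a_general
        if self.group_index > 0:
            a[self.group_index] = self.a_group
        return a


@dataclass
class ItemBank:
    """Ordered collection of :class:`ItemParameters` plus the factor layout."""

    items: list[ItemParameters]
    G: int

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate item_ids in bank")
        for it in self.items:
            if it.group_index > self.G:
                raise InvalidInputError(
                    f"item {it.item_id!r}: group_index {it.group_index} > G={self.G}")

    @property
    def D(self) -> int:
        return self.G + 1

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def index_of(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    # ---- cached dense arrays used by the vectorized kernels -------------

    @cached_property
    def loadings(self) -> np.ndarray:
        """(n_items, D) loading matrix."""
        A = np.zeros((self.n_items, self.D))
        for i, it in enumerate(self.items):
            A[i] = it.loading_vector(self.D)
        return A

    @cached_property
    def group_indices(self) -> np.ndarray:
        return np.array([it.group_index for it in self.items], dtype=int)

    @cached_property
    def n_categories(self) -> np.ndarray:
        return np.array([it.n_categories for it in self.items], dtype=int)

    @cached_property
    def max_categories(self) -> int:
        return int(self.n_categories.max())

    @cached_property
    def padded_intercepts(self) -> np.ndarray:
        """(n_items, Kmax-1) intercepts padded with -inf.

        A -inf boundary contributes a boundary probability of exactly 0, so
        padded categories get probability 0 and every vectorized formula
        stays valid for mixed response formats.
        """
        Km1 = self.max_categories - 1
        d = np.full((self.n_items, Km1), -np.inf)
        for i, it in enumerate(self.items):
            d[i, : it.intercepts.size] = it.intercepts
        return d

    def subset(self, indices: Sequence[int]) -> "ItemBank":
        """New bank with the selected items (same factor layout)."""
        return ItemBank(items=[self.items[i] for i in indices], G=self.G)


# ----------------------------------------------------------------------
# scalar/padded kernels
# ----------------------------------------------------------------------


def _check_theta(theta: np.ndarray, D: int) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (D,):
        raise InvalidInputError(f"theta must have shape ({D},), got {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise InvalidInputError("theta has non-finite entries")
    return theta


def _boundary_probs(z, intercepts):
    """P*_k = logistic(z + d_k) for the interior boundaries (broadcasting)."""
    return expit(np.asarray(z)[..., None] + intercepts)


def _cat_probs_from_boundary(pstar):
    """Category probabilities from interior boundary probabilities.

    ``pstar`` has shape (..., K-1); returns (..., K) via the telescoping
    differences with implicit P*_0 = 1 and P*_K = 0.
    """
    shape = pstar.shape[:-1]
    ones = np.ones(shape + (1,))
    zeros = np.zeros(shape + (1,))
    full = np.concatenate([ones, pstar, zeros], axis=-1)
    return -np.diff(full, axis=-1)


def _grm_weight(pstar, probs):
    """Fisher-information weight w(z) = sum_k (q_k - q_{k+1})^2 / P_k.

    ``q_k = P*_k (1 - P*_k)`` with q_0 = q_K = 0.  The item information
    matrix is then ``w(z) * a a^T``.
    """
    q = pstar * (1.0 - pstar)
    shape = q.shape[:-1]
    zeros = np.zeros(shape + (1,))
    qfull = np.concatenate([zeros, q, zeros], axis=-1)
    dP = -np.diff(qfull, axis=-1)  # dP_k/dz = q_k - q_{k+1}
    return np.sum(dP**2 / np.maximum(probs, PROB_FLOOR), axis=-1)


# ----------------------------------------------------------------------
# public per-item operations
# ----------------------------------------------------------------------


def category_probabilities(item: ItemParameters, theta: np.ndarray,
                           D: int | None = None) -> np.ndarray:
    """Category probabilities P_0..P_{K-1} for one item at one theta.

    ``D`` defaults to ``max(group_index, 0) + 1`` inferred from theta's
    length; pass it explicitly when scoring against a bank.
    """
    theta = np.asarray(theta, dtype=float)
    if D is None:
        D = theta.size
    theta = _check_theta(theta, D)
    if item.group_index >= D:
        raise InvalidInputError(
            f"item {item.item_id!r}: group_index {item.group_index} outside theta dimension {D}")
    z = item.a_general * theta[0]
    if item.group_index > 0:
        z += item.a_group * theta[item.group_index]
    pstar = _boundary_probs(z, item.intercepts)
    return _cat_probs_from_boundary(pstar)


def item_information(item: ItemParameters, theta: np.ndarray,
                     D: int | None = None) -> np.ndarray:
    """Expected (Fisher) information matrix of one item at ``theta``.

    Rank <= 1, supported only on dimensions {0, group_index}.
    """
    theta = np.asarray(theta, dtype=float)
    if D is None:
        D = theta.size
    theta = _check_theta(theta, D)
    z = item.a_general * theta[0]
    if item.group_index > 0:
        z += item.a_group * theta[item.group_index]
    pstar = _boundary_probs(z, item.intercepts)
    probs = _cat_probs_from_boundary(pstar)
    w = _grm_weight(pstar, probs)
    a = item.loading_vector(D)
    return float(w) * np.outer(a, a)


def expected_item_score(item: ItemParameters, theta: np.ndarray,
                        D: int | None = None) -> float:
    """Model-implied expected response E(x) = sum_k k * P_k(theta)."""
    probs = category_probabilities(item, theta, D=D)
    return float(np.dot(np.arange(probs.size), probs))


def pattern_log_likelihood(pattern: np.ndarray, theta: np.ndarray,
                           bank: ItemBank) -> float:
    """Log-likelihood of a (partial) response pattern at ``theta``.

    ``pattern`` is an integer array aligned with ``bank.items``; missing
    responses are marked with -1 (or NaN in a float array) and contribute
    nothing to the sum — the full-information treatment of missingness.
    """
    x = _coerce_pattern(pattern, bank)
    theta = _check_theta(theta, bank.D)
    obs = np.flatnonzero(x >= 0)
    if obs.size == 0:
        return 0.0
    logp, _, _ = _pattern_terms(x, theta, bank, obs)
    return float(logp)


def _coerce_pattern(pattern, bank: ItemBank) -> np.ndarray:
    arr = np.asarray(pattern)
    if arr.shape != (bank.n_items,):
        raise InvalidInputError(
            f"pattern must have length {bank.n_items}, got shape {arr.shape}")
    if arr.dtype.kind == "f":
        x = np.where(np.isnan(arr), MISSING, arr).astype(int)
    else:
        x = arr.astype(int)
    bad = (x >= 0) & (x > bank.n_categories - 1)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise InvalidInputError(
            f"response {x[i]} out of range for item {bank.item_ids[i]!r} "
            f"(K={bank.n_categories[i]})")
    if np.any(x < MISSING):
        raise InvalidInputError("negative response category (other than the -1 missing marker)")
    return x


def _pattern_terms(x, theta, bank: ItemBank, obs):
    """Shared kernel: per-observed-item log P, dlogP/dz, d2logP/dz2."""
    z = bank.loadings[obs] @ theta
    d = bank.padded_intercepts[obs]
    pstar = expit(z[:, None] + d)
    probs = _cat_probs_from_boundary(pstar)
    k = x[obs]
    rows = np.arange(obs.size)
    P = np.maximum(probs[rows, k], PROB_FLOOR)

    q = pstar * (1.0 - pstar)
    zeros = np.zeros((obs.size, 1))
    qfull = np.concatenate([zeros, q, zeros], axis=-1)
    dP = -np.diff(qfull, axis=-1)           # dP_k/dz
    dq = q * (1.0 - 2.0 * pstar)            # dq_k/dz
    dqfull = np.concatenate([zeros, dq, zeros], axis=-1)
    d2P = -np.diff(dqfull, axis=-1)         # d2P_k/dz2

    u = dP[rows, k] / P                     # dlogP/dz
    c = d2P[rows, k] / P - u**2             # d2logP/dz2
    return np.sum(np.log(P)), u, c


# ----------------------------------------------------------------------
# parameter-dialect conversion
# ----------------------------------------------------------------------


def intercepts_from_difficulties(a_general: float, a_group: float,
                                 difficulties) -> np.ndarray:
    """Convert difficulty-style thresholds b_k to intercepts d_k = -b_k * ||a||."""
    b = np.asarray(difficulties, dtype=float)
    if b.size > 1 and not np.all(np.diff(b) > 0):
        raise InvalidInputError(f"difficulties must be strictly increasing, got {b}")
    norm = float(np.hypot(a_general, a_group))
    if norm <= 0:
        raise InvalidInputError("zero loading vector has no difficulty parameterization")
    return -b * norm


def difficulties_from_intercepts(a_general: float, a_group: float,
                                 intercepts) -> np.ndarray:
    """Inverse of :func:`intercepts_from_difficulties`."""
    d = np.asarray(intercepts, dtype=float)
    norm = float(np.hypot(a_general, a_group))
    if norm <= 0:
        raise InvalidInputError("zero loading vector has no difficulty parameterization")
    return -d / norm
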