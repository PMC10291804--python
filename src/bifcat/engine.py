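"""The MCAT loop: determinant-rule item selection, stopping rules, batch runs.

Item selection uses the DP-rule: among unadministered items, pick the one
maximizing the determinant of the posterior information matrix after
hypothetically adding that item's Fisher information at the current trait
estimate.  Because each item's information is rank one (``w * a a^T``),
the determinant update is

    det(J + w a a^T) = det(J) * (1 + w * a^T J^-1 a),

so the argmax reduces to maximizing ``w_i * a_i^T J^-1 a_i``.  The engine
is fully deterministic: all stochasticity lives in the synthetic-data
generators, and responses are read from a pre-simulated matrix.

Stopping follows a factorial design over three criteria: an SE threshold
on the general factor, an SE threshold applied to every group factor, and
a minimal change in the trait estimate from one item to the next.  The SE
rule fires only when the general-factor SE and (when a group threshold is
set) every group-factor SE have dropped strictly below their thresholds;
the change rule fires when the trait estimate moved by less than the
threshold on every dimension; the rules combine as a disjunction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import InvalidInputError, ItemBank, MISSING
from .scoring import PosteriorState, map_estimate, posterior_information, standard_errors

__all__ = [
    "TerminationPolicy", "SimulationDesign", "AdministrationRecord",
    "select_next_item", "check_termination", "administer_respondent", "run_design",
    "factorial_design",
]


@dataclass(frozen=True)
class TerminationPolicy:
    """One stopping-rule configuration (a row of the simulation design).

    ``None`` disables a criterion; a policy with every criterion disabled
    administers the whole bank ("full" run).
    """

    name: str
    se_general: float | None = None
    se_group: float | None = None
    theta_change: float | None = None
    max_items: int | None = None

    def __post_init__(self) -> None:
        for attr in ("se_general", "se_group", "theta_change"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise InvalidInputError(f"{attr} must be positive, got {v}")
        if self.max_items is not None and self.max_items < 1:
            raise InvalidInputError("max_items must be >= 1")


@dataclass
class SimulationDesign:
    """Named collection of termination policies, run row by row."""

    rows: list[TerminationPolicy]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate design row names")

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, name: str) -> TerminationPolicy:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def factorial_design() -> SimulationDesign:
    """The bundled 2x2x2 stopping-rule factorial plus the no-rule "full" row.

    General-factor SE threshold 0.32 (reliability 0.90) or 0.40 (0.85);
    group-factor SE threshold 0.50 (reliability 0.75) or absent; trait
    change threshold 0.01 or absent.
    """
    rows = [TerminationPolicy(name="full")]
    i = 0
    for se_gen in (0.32, 0.40):
        for se_grp in (0.50, None):
            for change in (None, 0.01):
                i += 1
                rows.append(TerminationPolicy(
                    name=f"sim{i}", se_general=se_gen,
                    se_group=se_grp, theta_change=change))
    return SimulationDesign(rows=rows)


@dataclass
class AdministrationRecord:
    """Outcome of one adaptive administration for one respondent."""

    respondent: int
    item_ids: list[str]
    responses: list[int]
    theta_hat: np.ndarray
    se: np.ndarray
    stop_reason: str  # "se_rule" | "change_rule" | "exhausted"
    theta_history: np.ndarray  # (n_administered, D)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


def _dp_scores(state_info_inv: np.ndarray, w: np.ndarray, bank: ItemBank) -> np.ndarray:
    """Vectorized ``w_i * a_i^T J^-1 a_i`` for every bank item."""
    ag = bank.loadings[:, 0]
    g = bank.group_indices
    agr = bank.loadings[np.arange(bank.n_items), np.where(g > 0, g, 0)]
    agr = np.where(g > 0, agr, 0.0)
    M = state_info_inv
    quad = ag**2 * M[0, 0] + 2.0 * ag * agr * M[0, g] + agr**2 * M[g, g]
    return w * quad


def _all_weights(theta: np.ndarray, bank: ItemBank) -> np.ndarray:
    from .grm import _boundary_probs, _cat_probs_from_boundary, _grm_weight
    z = bank.loadings @ theta
    pstar = _boundary_probs(z, bank.padded_intercepts)
    return _grm_weight(pstar, _cat_probs_from_boundary(pstar))


def select_next_item(state: PosteriorState, bank: ItemBank) -> str:
    """DP-rule selection among unadministered items (ties -> lowest bank index).

    With an empty state this evaluates at the prior mode with prior-only
    information, so the starting item is identical for every respondent.
    """
    admin = set(state.administered)
    candidates = [i for i, iid in enumerate(bank.item_ids) if iid not in admin]
    if not candidates:
        raise InvalidInputError("no unadministered items left")
    w = _all_weights(state.theta_hat, bank)
    scores = _dp_scores(np.linalg.inv(state.info), w, bank)
    cand = np.array(candidates)
    best = cand[int(np.argmax(scores[cand]))]
    return bank.item_ids[best]


def check_termination(state: PosteriorState, policy: TerminationPolicy,
                      bank_size: int) -> tuple[bool, str | None]:
    """Evaluate the stopping rules after the latest response/rescore.

    Thresholds use strict inequalities ("dropped below").  The change rule
    needs at least two administered items so a previous estimate exists.
    """
    m = len(state.administered)
    if m == 0:
        return False, None
    se_ok = False
    if policy.se_general is not None:
        se_ok = state.se[0] < policy.se_general
        if se_ok and policy.se_group is not None:
            se_ok = bool(np.all(state.se[1:] < policy.se_group))
    if se_ok:
        return True, "se_rule"
    if policy.theta_change is not None and m >= 2:
        delta = np.max(np.abs(state.theta_history[-1] - state.theta_history[-2]))
        if delta < policy.theta_change:
            return True, "change_rule"
    max_items = policy.max_items if policy.max_items is not None else bank_size
    if m >= min(max_items, bank_size):
        return True, "exhausted"
    return False, None


def administer_respondent(true_responses: np.ndarray, bank: ItemBank,
                          policy: TerminationPolicy,
                          respondent: int = 0) -> AdministrationRecord:
    """Run the adaptive loop for one respondent against pre-simulated responses.

    Loop: select by the DP-rule, read the response from ``true_responses``,
    re-estimate theta by MAP on the administered subset, recompute the
    posterior information and SEs at the new estimate, then check the
    stopping rules.  Deterministic given (responses, bank, policy).
    """
    x_full = np.asarray(true_responses)
    if x_full.shape != (bank.n_items,):
        raise InvalidInputError(
            f"true_responses must have length {bank.n_items}")
    if np.any(x_full < 0):
        raise InvalidInputError("true_responses must be complete (no missing)")

    D = bank.D
    state = PosteriorState(theta_hat=np.zeros(D), info=np.eye(D),
                           se=np.ones(D))
    pattern = np.full(bank.n_items, MISSING, dtype=int)
    idx_of = {iid: i for i, iid in enumerate(bank.item_ids)}

    while True:
        item_id = select_next_item(state, bank)
        i = idx_of[item_id]
        pattern[i] = x_full[i]
        state.administered.append(item_id)
        state.responses.append(int(x_full[i]))
        state.theta_hat = map_estimate(pattern, bank, start=state.theta_hat)
        state.info = posterior_information(state.theta_hat, pattern, bank)
        state.se = standard_errors(state.info)
        state.theta_history.append(state.theta_hat.copy())
        stop, reason = check_termination(state, policy, bank.n_items)
        if stop:
            return AdministrationRecord(
                respondent=respondent,
                item_ids=list(state.administered),
                responses=list(state.responses),
                theta_hat=state.theta_hat.copy(),
                se=state.se.copy(),
                stop_reason=reason,
                theta_history=np.array(state.theta_history),
            )


def run_design(design: SimulationDesign, bank: ItemBank, thetas: np.ndarray,
               responses: np.ndarray) -> dict[str, list[AdministrationRecord]]:
    """Administer every respondent under every design row.

    ``thetas`` is carried along only for shape validation and downstream
    evaluation; the engine itself reads nothing but ``responses``.
    Identical inputs yield identical outputs — the engine draws no random
    numbers.
    """
    thetas = np.asarray(thetas, dtype=float)
    responses = np.asarray(responses)
    if thetas.ndim != 2 or thetas.shape[1] != bank.D:
        raise InvalidInputError(f"thetas must be (n, {bank.D})")
    if responses.shape != (thetas.shape[0], bank.n_items):
        raise InvalidInputError(
            f"responses must be (n, {bank.n_items}), got {responses.shape}")
    out: dict[str, list[AdministrationRecord]] = {}
    for policy in design:
        out[policy.name] = [
            administer_respondent(responses[j], bank, policy, respondent=j)
            for j in range(responses.shape[0])
        ]
    return out
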