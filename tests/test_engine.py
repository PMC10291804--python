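"""Determinant-rule selection, stopping rules, and the adaptive loop."""

import numpy as np
import pytest

import bifcat as bc
from bifcat.grm import InvalidInputError, MISSING
from bifcat.scoring import PosteriorState
from oracles import select_by_full_determinant


def fresh_state(D):
    return PosteriorState(theta_hat=np.zeros(D), info=np.eye(D), se=np.ones(D))


class TestSelectNextItem:
    def test_single_candidate_selected(self, small_bank):
        state = fresh_state(3)
        state.administered = ["a", "b", "c"]
        assert bc.select_next_item(state, small_bank) == "d"

    def test_empty_candidate_set_rejected(self, small_bank):
        state = fresh_state(3)
        state.administered = ["a", "b", "c", "d"]
        with pytest.raises(InvalidInputError):
            bc.select_next_item(state, small_bank)

    def test_dominating_slopes_win(self):
        weak = bc.ItemParameters("weak", 1, 0.8, 0.5, np.array([0.3]))
        strong = bc.ItemParameters("strong", 1, 1.6, 1.0, np.array([0.3]))
        bank = bc.ItemBank([weak, strong], G=1)
        assert bc.select_next_item(fresh_state(2), bank) == "strong"

    def test_matches_brute_force_determinant_enumeration(self, default_bank):
        rng = np.random.default_rng(42)
        state = fresh_state(default_bank.D)
        state.theta_hat = rng.uniform(-1, 1, default_bank.D)
        state.info = bc.posterior_information(
            state.theta_hat,
            np.where(rng.random(default_bank.n_items) < 0.3,
                     rng.integers(0, 2, default_bank.n_items), MISSING),
            default_bank)
        got = bc.select_next_item(state, default_bank)
        want = select_by_full_determinant(state.info, state.theta_hat,
                                          default_bank, set())
        assert got == want

    def test_first_item_identical_across_respondents(self, default_bank, design_results):
        firsts = {rec.item_ids[0] for rec in design_results["sim3"]}
        assert len(firsts) == 1

    def test_rank_one_determinant_update_identity(self, default_bank):
        # det(A + w aa^T) = det(A) (1 + w a^T A^-1 a) on a nontrivial state
        rng = np.random.default_rng(1)
        M = rng.standard_normal((default_bank.D, default_bank.D))
        A = np.eye(default_bank.D) + M @ M.T
        item = default_bank.items[7]
        theta = rng.uniform(-1, 1, default_bank.D)
        info_i = bc.item_information(item, theta)
        a = item.loading_vector(default_bank.D)
        w = info_i[0, 0] / a[0] ** 2
        lhs = np.linalg.det(A + info_i)
        rhs = np.linalg.det(A) * (1 + w * a @ np.linalg.inv(A) @ a)
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestCheckTermination:
    def policy(self, **kw):
        return bc.TerminationPolicy(name="p", **kw)

    def state_with(self, se, history):
        s = fresh_state(len(se))
        s.se = np.asarray(se, dtype=float)
        s.theta_history = [np.asarray(h, dtype=float) for h in history]
        s.administered = [f"i{k}" for k in range(len(history))]
        return s

    def test_general_se_rule_alone_stops(self):
        s = self.state_with([0.30, 0.9, 0.9], [[0.0, 0, 0]])
        stop, reason = bc.check_termination(s, self.policy(se_general=0.32), 44)
        assert stop and reason == "se_rule"

    def test_group_se_above_threshold_blocks_stop(self):
        s = self.state_with([0.30, 0.60, 0.4], [[0.0, 0, 0]])
        stop, _ = bc.check_termination(
            s, self.policy(se_general=0.32, se_group=0.50), 44)
        assert not stop

    def test_change_rule_fires_as_disjunction(self):
        s = self.state_with([0.50, 0.9, 0.9],
                            [[0.100, 0, 0], [0.105, 0.001, 0.0]])
        stop, reason = bc.check_termination(
            s, self.policy(se_general=0.32, theta_change=0.01), 44)
        assert stop and reason == "change_rule"

    def test_change_rule_needs_two_items(self):
        s = self.state_with([0.50, 0.9, 0.9], [[0.0, 0, 0]])
        stop, _ = bc.check_termination(
            s, self.policy(se_general=0.32, theta_change=0.01), 44)
        assert not stop

    def test_change_rule_uses_all_dimensions(self):
        s = self.state_with([0.50, 0.9, 0.9],
                            [[0.100, 0.5, 0], [0.101, 0.55, 0.0]])
        stop, _ = bc.check_termination(
            s, self.policy(se_general=0.32, theta_change=0.01), 44)
        assert not stop  # a group dimension moved by 0.05

    def test_exhaustion(self):
        s = self.state_with([0.9, 0.9, 0.9], [[0, 0, 0]] * 3)
        stop, reason = bc.check_termination(s, self.policy(se_general=0.01), 3)
        assert stop and reason == "exhausted"

    def test_strict_inequality_at_threshold(self):
        s = self.state_with([0.32, 0.9, 0.9], [[0.0, 0, 0]])
        stop, _ = bc.check_termination(s, self.policy(se_general=0.32), 44)
        assert not stop


class TestAdministerRespondent:
    def test_full_policy_exhausts_bank(self, default_bank, design_results):
        for rec in design_results["full"][:50]:
            assert rec.n_items == default_bank.n_items
            assert rec.stop_reason == "exhausted"
            assert len(set(rec.item_ids)) == rec.n_items

    def test_stop_step_matches_independent_se_replay(self, default_bank, design_data):
        """Under the general-SE rule the loop stops at exactly the first step
        where the replayed SE drops below threshold."""
        _, responses = design_data
        policy = bc.factorial_design()["sim3"]
        rec = bc.administer_respondent(responses[3], default_bank, policy, 3)
        x = np.full(default_bank.n_items, MISSING)
        stop_step = None
        for step, iid in enumerate(rec.item_ids, start=1):
            i = default_bank.index_of(iid)
            x[i] = responses[3, i]
            theta = bc.map_estimate(x, default_bank)
            se = bc.standard_errors(bc.posterior_information(theta, x, default_bank))
            if se[0] < 0.32:
                stop_step = step
                break
        assert stop_step == rec.n_items
        assert rec.stop_reason == "se_rule"

    def test_missing_responses_rejected(self, default_bank):
        x = np.full(default_bank.n_items, MISSING)
        with pytest.raises(InvalidInputError):
            bc.administer_respondent(x, default_bank, bc.TerminationPolicy(name="f"))


class TestRunDesign:
    def test_one_record_per_respondent_per_row(self, design_results, design_data):
        thetas, _ = design_data
        assert set(design_results) == {"full"} | {f"sim{i}" for i in range(1, 9)}
        for recs in design_results.values():
            assert len(recs) == thetas.shape[0]

    def test_engine_is_deterministic(self, default_bank, design_data):
        thetas, responses = design_data
        design = bc.SimulationDesign(rows=[bc.factorial_design()["sim7"]])
        r1 = bc.run_design(design, default_bank, thetas[:20], responses[:20])
        r2 = bc.run_design(design, default_bank, thetas[:20], responses[:20])
        for a, b in zip(r1["sim7"], r2["sim7"]):
            assert a.item_ids == b.item_ids
            assert np.array_equal(a.theta_hat, b.theta_hat)

    def test_group_se_rule_never_shortens_administration(self, design_results):
        """Adding the group-SE requirement can only delay stopping."""
        with_group = np.array([r.n_items for r in design_results["sim1"]])
        without = np.array([r.n_items for r in design_results["sim3"]])
        assert np.all(with_group >= without)


class TestFactorialDesign:
    def test_nine_rows_with_factorial_layout(self):
        design = bc.factorial_design()
        assert len(design.rows) == 9
        full = design["full"]
        assert full.se_general is None and full.se_group is None
        assert design["sim1"].se_general == 0.32
        assert design["sim1"].se_group == 0.50
        assert design["sim1"].theta_change is None
        assert design["sim4"].theta_change == 0.01
        assert design["sim5"].se_general == 0.40
        assert design["sim8"].se_group is None

    def test_duplicate_row_names_rejected(self):
        with pytest.raises(InvalidInputError):
            bc.SimulationDesign(rows=[bc.TerminationPolicy(name="a"),
                                      bc.TerminationPolicy(name="a")])
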