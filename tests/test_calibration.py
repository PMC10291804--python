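"""EM calibration, Yen's Q3 screening, and fit summaries."""

import numpy as np
import pytest

import bifcat as bc
from bifcat.calibration import (
    EstimationSettings,
    item_information_scalar,
    q3_matrix,
    screen_local_dependence,
    srmsr,
)
from bifcat.grm import InvalidInputError


class TestFitBifactorGrm:
    def test_parameter_recovery(self, recovery_truth, recovery_fit):
        truth, _ = recovery_truth
        est = recovery_fit.bank
        t_slopes = np.concatenate([[it.a_general for it in truth.items],
                                   [it.a_group for it in truth.items]])
        e_slopes = np.concatenate([[it.a_general for it in est.items],
                                   [it.a_group for it in est.items]])
        assert np.corrcoef(t_slopes, e_slopes)[0, 1] >= 0.95
        errs = np.concatenate([np.abs(t.intercepts - e.intercepts)
                               for t, e in zip(truth.items, est.items)])
        assert errs.mean() <= 0.15

    def test_em_ascent(self, recovery_fit):
        traj = recovery_fit.log_likelihood_trajectory
        assert np.all(np.diff(traj) >= -1e-8)
        assert recovery_fit.converged

    def test_reduces_to_unidimensional_estimator(self, unidimensional_fits):
        """With every item assigned to the general factor the estimator must
        agree with an independently coded 1-D GRM EM."""
        reduced, (a_uni, d_uni, _) = unidimensional_fits
        assert reduced.bank.D == 1
        for i, it in enumerate(reduced.bank.items):
            assert abs(it.a_general - a_uni[i]) < 0.05
            assert np.max(np.abs(it.intercepts - d_uni[i])) < 0.05

    def test_missing_entries_tolerated(self, recovery_truth):
        bank, structure = recovery_truth
        thetas = bc.generate_thetas(400, bank.D, seed=61)
        x = bc.simulate_responses(thetas, bank, seed=62, missing_rate=0.15)
        res = bc.fit_bifactor_grm(x, structure, EstimationSettings(max_cycles=5))
        assert len(res.bank.items) == bank.n_items
        assert np.all(np.diff(res.log_likelihood_trajectory) >= -1e-8)

    def test_unobserved_category_collapsed_with_warning(self, recovery_truth):
        bank, structure = recovery_truth
        thetas = bc.generate_thetas(300, bank.D, seed=63)
        x = bc.simulate_responses(thetas, bank, seed=64)
        # item 2 has K=5: empty category 2 by pushing responses upward
        x[:, 2] = np.where(x[:, 2] == 2, 3, x[:, 2])
        with pytest.warns(UserWarning, match="collapsing"):
            res = bc.fit_bifactor_grm(x, structure, EstimationSettings(max_cycles=2))
        assert res.bank.items[2].n_categories == 4
        with pytest.raises(InvalidInputError):
            bc.fit_bifactor_grm(
                x, structure,
                EstimationSettings(max_cycles=2, on_unobserved_category="error"))

    def test_nonconvergence_is_flagged(self, recovery_truth):
        bank, structure = recovery_truth
        thetas = bc.generate_thetas(300, bank.D, seed=65)
        x = bc.simulate_responses(thetas, bank, seed=66)
        res = bc.fit_bifactor_grm(x, structure, EstimationSettings(max_cycles=2))
        assert not res.converged
        assert res.n_cycles == 2


class TestQ3:
    def test_type_one_behaviour_under_local_independence(self, recovery_truth,
                                                         recovery_data):
        bank, _ = recovery_truth
        _, responses = recovery_data
        q3 = q3_matrix(responses, bank)
        off = q3.to_numpy()[np.triu_indices(bank.n_items, 1)]
        assert np.mean(np.abs(off) > 0.20) < 0.01
        assert np.nanmax(off) < 0.10  # signed flagging statistic stays small

    def test_symmetry_and_range(self, recovery_truth, recovery_data):
        bank, _ = recovery_truth
        _, responses = recovery_data
        q3 = q3_matrix(responses, bank).to_numpy()
        assert np.allclose(q3, q3.T, equal_nan=True)
        finite = q3[~np.isnan(q3)]
        assert np.all((finite >= -1) & (finite <= 1))

    def test_duplicated_item_is_flagged_and_weaker_copy_removed(
            self, recovery_truth, recovery_data):
        bank, _ = recovery_truth
        _, responses = recovery_data
        src = bank.items[0]
        dup = bc.ItemParameters("dup", src.group_index, src.a_general * 0.9,
                                src.a_group * 0.9, src.intercepts.copy())
        bank2 = bc.ItemBank(bank.items + [dup], G=bank.G)
        x2 = np.column_stack([responses, responses[:, 0]])
        q3 = q3_matrix(x2, bank2)
        assert q3.loc[src.item_id, "dup"] > 0.20
        report = screen_local_dependence(q3, bank2)
        assert (src.item_id, "dup") in {(a, b) for a, b, _ in report.flagged_pairs}
        assert report.removed == ["dup"]

    def test_sparse_pair_flagged_unavailable(self, small_bank):
        x = np.full((10, 4), -1)
        x[:, 0] = [0, 1] * 5
        x[:2, 1] = [1, 0]  # only 2 joint observations with item 0
        x[:, 2] = [1, 0] * 5
        x[:, 3] = [0, 1, 2, 3, 0, 1, 2, 3, 0, 1]
        q3 = q3_matrix(x, small_bank)
        assert np.isnan(q3.loc["a", "b"])
        assert not np.isnan(q3.loc["a", "c"])


class TestScreening:
    def test_nothing_flagged_below_threshold(self, recovery_truth, recovery_data):
        bank, _ = recovery_truth
        _, responses = recovery_data
        report = screen_local_dependence(q3_matrix(responses, bank), bank)
        assert report.flagged_pairs == []
        assert report.removed == []

    def test_published_pair_replay_reproduces_removal_set(self):
        """Greedy descending-Q3 resolution of the ten reported flagged pairs,
        with an information ordering consistent with the reported outcome,
        removes exactly items 5, 6, 9, 11, 20, 29, 45, 54."""
        pairs = [("5", "10"), ("30", "54"), ("9", "10"), ("6", "7"),
                 ("4", "5"), ("10", "11"), ("44", "45"), ("20", "33"),
                 ("29", "31"), ("53", "54")]
        ids = sorted({i for p in pairs for i in p}, key=int)
        import pandas as pd
        q3 = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
        for rank, (a, b) in enumerate(pairs):
            q3.loc[a, b] = q3.loc[b, a] = 0.50 - 0.02 * rank
        np.fill_diagonal(q3.values, np.nan)
        # information ordering: each removed member weaker than its partner
        info = {"5": 1.0, "10": 3.0, "54": 0.5, "30": 2.0, "9": 1.2, "6": 0.8,
                "7": 2.1, "4": 1.9, "11": 1.1, "44": 2.4, "45": 0.9,
                "20": 0.7, "33": 2.2, "29": 1.3, "31": 2.6, "53": 2.8}
        items = [bc.ItemParameters(i, 0, 1.0, 0.0, np.array([0.0])) for i in ids]
        bank = bc.ItemBank(items, G=0)
        report = screen_local_dependence(q3, bank, information=info)
        assert sorted(report.removed, key=int) == ["5", "6", "9", "11",
                                                   "20", "29", "45", "54"]
        # every flagged pair ends with at least one member removed
        for a, b, _ in report.flagged_pairs:
            assert a in report.removed or b in report.removed

    def test_result_invariant_to_tied_pair_input_order(self):
        import pandas as pd
        ids = ["w", "x", "y", "z"]
        q3 = pd.DataFrame(np.zeros((4, 4)), index=ids, columns=ids)
        q3.loc["w", "x"] = q3.loc["x", "w"] = 0.30
        q3.loc["y", "z"] = q3.loc["z", "y"] = 0.30
        np.fill_diagonal(q3.values, np.nan)
        info = {"w": 1.0, "x": 2.0, "y": 2.0, "z": 1.0}
        items = [bc.ItemParameters(i, 0, 1.0, 0.0, np.array([0.0])) for i in ids]
        r1 = screen_local_dependence(q3, bc.ItemBank(items, G=0), information=info)
        r2 = screen_local_dependence(q3.loc[ids[::-1], ids[::-1]],
                                     bc.ItemBank(items[::-1], G=0), information=info)
        assert sorted(r1.removed) == sorted(r2.removed) == ["w", "z"]


class TestItemInformationScalar:
    def test_vanishes_with_vanishing_slopes(self):
        item = bc.ItemParameters("tiny", 0, 1e-6, 0.0, np.array([0.0]))
        assert item_information_scalar(item) < 1e-10

    def test_doubling_slopes_increases_information(self):
        base = bc.ItemParameters("b", 1, 1.0, 0.8, np.array([0.5, -0.5]))
        double = bc.ItemParameters("d", 1, 2.0, 1.6, np.array([0.5, -0.5]))
        assert item_information_scalar(double) > item_information_scalar(base)

    def test_centered_item_beats_tail_item(self):
        centered = bc.ItemParameters("c", 0, 1.5, 0.0, np.array([0.5, -0.5]))
        tail = bc.ItemParameters("t", 0, 1.5, 0.0, np.array([-4.0, -5.0]))
        assert item_information_scalar(centered) > item_information_scalar(tail)


class TestSrmsr:
    def test_small_for_correctly_specified_model(self, recovery_truth, recovery_data):
        bank, _ = recovery_truth
        _, responses = recovery_data
        assert srmsr(responses, bank) < 0.03

    def test_inflated_by_injected_dependence(self, recovery_truth, recovery_data):
        bank, _ = recovery_truth
        _, responses = recovery_data
        clean = srmsr(responses, bank)
        x = responses.copy()
        K1 = bank.items[1].n_categories
        x[:, 1] = np.minimum(x[:, 0], K1 - 1)  # item 1 now echoes item 0
        assert srmsr(x, bank) > clean
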