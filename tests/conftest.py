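"""Shared fixtures.

The expensive computations (EM fits, the nine-row design run) are
session-scoped so each runs once and is shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import bifcat as bc
from bifcat.calibration import EstimationSettings


@pytest.fixture(scope="session")
def default_bank() -> bc.ItemBank:
    """The default synthetic 44-item, 10-group bank."""
    return bc.generate_item_bank(bc.BankSpec(seed=3))


@pytest.fixture(scope="session")
def design_data(default_bank):
    """1000 MVN(0, I_11) respondents and their complete response matrix."""
    thetas = bc.generate_thetas(1000, default_bank.D, seed=11)
    responses = bc.simulate_responses(thetas, default_bank, seed=12)
    return thetas, responses


@pytest.fixture(scope="session")
def design_results(default_bank, design_data):
    """All nine design rows administered to the 1000 simulated respondents."""
    thetas, responses = design_data
    return bc.run_design(bc.factorial_design(), default_bank, thetas, responses)


def _recovery_truth():
    """20-item, 2-group truth bank with slopes in [0.9, 2.5] and mixed formats."""
    rng = np.random.default_rng(5)
    items, structure = [], {}
    for i in range(20):
        g = 1 if i < 10 else 2
        a_gen = rng.uniform(0.9, 2.5)
        a_grp = rng.uniform(0.9, 2.5)
        K = [2, 3, 5][i % 3]
        b = np.sort(rng.uniform(-2, 2, K - 1))
        while K > 2 and np.any(np.diff(b) < 0.3):
            b = np.sort(rng.uniform(-2, 2, K - 1))
        d = bc.intercepts_from_difficulties(a_gen, a_grp, b)
        iid = f"it{i}"
        items.append(bc.ItemParameters(iid, g, a_gen, a_grp, d))
        structure[iid] = g
    return bc.ItemBank(items, G=2), structure


@pytest.fixture(scope="session")
def recovery_truth():
    return _recovery_truth()


@pytest.fixture(scope="session")
def recovery_data(recovery_truth):
    """n=2000 complete responses from the recovery truth bank."""
    bank, _ = recovery_truth
    thetas = bc.generate_thetas(2000, bank.D, seed=21)
    responses = bc.simulate_responses(thetas, bank, seed=22)
    return thetas, responses


@pytest.fixture(scope="session")
def recovery_fit(recovery_truth, recovery_data):
    bank, structure = recovery_truth
    _, responses = recovery_data
    return bc.fit_bifactor_grm(responses, structure)


def _unidimensional_truth():
    """16 general-only items: every group slope is exactly zero."""
    rng = np.random.default_rng(14)
    items, structure = [], {}
    for i in range(16):
        a_gen = rng.uniform(1.2, 2.2)
        b = np.linspace(-1.6, 1.6, 4) + rng.uniform(-0.25, 0.25, 4)
        d = bc.intercepts_from_difficulties(a_gen, 0.0, b)
        iid = f"u{i}"
        items.append(bc.ItemParameters(iid, 0, a_gen, 0.0, d))
        structure[iid] = 0
    return bc.ItemBank(items, G=0), structure


@pytest.fixture(scope="session")
def unidimensional_truth():
    return _unidimensional_truth()


@pytest.fixture(scope="session")
def unidimensional_data(unidimensional_truth):
    bank, _ = unidimensional_truth
    thetas = bc.generate_thetas(3000, bank.D, seed=31)
    responses = bc.simulate_responses(thetas, bank, seed=32)
    return thetas, responses


@pytest.fixture(scope="session")
def unidimensional_fits(unidimensional_truth, unidimensional_data):
    """Package fit (general-only structure) and the independent 1-D EM oracle."""
    from oracles import fit_unidimensional_grm

    _, structure = unidimensional_truth
    _, responses = unidimensional_data
    reduced = bc.fit_bifactor_grm(responses, structure)
    a_uni, d_uni, ll_uni = fit_unidimensional_grm(responses)
    return reduced, (a_uni, d_uni, ll_uni)


@pytest.fixture()
def small_bank():
    """Hand-sized 4-item bank for kernel-level tests."""
    items = [
        bc.ItemParameters("a", 1, 1.2, 0.8, np.array([0.5])),
        bc.ItemParameters("b", 1, 1.5, 1.1, np.array([1.0, -0.5])),
        bc.ItemParameters("c", 2, 0.9, 1.3, np.array([0.2])),
        bc.ItemParameters("d", 2, 2.0, 0.7, np.array([1.5, 0.0, -1.0])),
    ]
    return bc.ItemBank(items, G=2)
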