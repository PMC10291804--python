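"""Synthetic latent traits, item banks, and GRM response matrices.

The generator emulates the study conditions of a bifactor MCAT simulation
for a 44-item health-related quality-of-life bank: 11 mutually
uncorrelated standard-normal latent traits (one general HRQOL factor plus
10 group factors), discriminations spanning the calibrated ranges
(0.92-4.71 general, 0.56-5.19 group), and boundary difficulties spread
over roughly [-2.5, 2.5] on the latent continuum, with the mixed 2- to
6-category response formats of the instrument.

Each public generator takes its own seed so the three streams (traits,
bank, responses) are independent: changing one leaves the others intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import (
    InvalidInputError,
    ItemBank,
    ItemParameters,
    _boundary_probs,
    _cat_probs_from_boundary,
    intercepts_from_difficulties,
)

__all__ = ["BankSpec", "generate_thetas", "generate_item_bank", "simulate_responses"]

# 44-item default layout: ten group factors with the post-screening item
# counts of the MSQOL-54 bifactor structure, plus three general-only items
# whose group assignment is treated as unresolved.
DEFAULT_STRUCTURE: tuple[tuple[str, int], ...] = (
    ("physical_function", 6),
    ("role_physical", 4),
    ("role_emotional", 3),
    ("pain", 3),
    ("emotional_wellbeing", 5),
    ("energy", 4),
    ("health_perceptions", 5),
    ("cognitive", 3),
    ("health_distress", 4),
    ("sexual_function", 4),
)

# mixed response formats, echoing the instrument: 3-point physical function,
# dichotomous role items, 5/6-point scales elsewhere
DEFAULT_CATEGORIES: dict[str, int] = {
    "physical_function": 3,
    "role_physical": 2,
    "role_emotional": 2,
    "pain": 5,
    "emotional_wellbeing": 6,
    "energy": 6,
    "health_perceptions": 5,
    "cognitive": 6,
    "health_distress": 5,
    "sexual_function": 5,
}
GENERAL_ONLY_CATEGORIES = 5


@dataclass
class BankSpec:
    """Recipe for a synthetic bifactor item bank."""

    structure: tuple[tuple[str, int], ...] = DEFAULT_STRUCTURE
    n_general_only: int = 3
    categories: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    a_general_range: tuple[float, float] = (0.92, 4.71)
    a_group_range: tuple[float, float] = (0.56, 5.19)
    difficulty_spread: tuple[float, float] = (-2.5, 2.5)
    seed: int = 0

    @property
    def G(self) -> int:
        return len(self.structure)

    @property
    def n_items(self) -> int:
        return sum(n for _, n in self.structure) + self.n_general_only

    def __post_init__(self) -> None:
        lo, hi = self.a_general_range
        if not (0 < lo <= hi):
            raise InvalidInputError("a_general_range must be positive and ordered")
        lo, hi = self.a_group_range
        if not (0 < lo <= hi):
            raise InvalidInputError("a_group_range must be positive and ordered")
        if self.difficulty_spread[0] >= self.difficulty_spread[1]:
            raise InvalidInputError("difficulty_spread must be ordered")
        for name, K in self.categories.items():
            if not 2 <= K <= 6:
                raise InvalidInputError(f"{name}: categories must be in 2..6, got {K}")


def generate_thetas(n: int, D: int, seed: int) -> np.ndarray:
    """Draw ``n`` trait vectors from MVN(0, I_D): independent standard normals."""
    if n < 1 or D < 1:
        raise InvalidInputError(f"need n >= 1 and D >= 1, got n={n}, D={D}")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, D))


def _spread_difficulties(rng: np.random.Generator, K: int,
                         spread: tuple[float, float]) -> np.ndarray:
    """K-1 strictly increasing difficulties with guaranteed minimum gaps."""
    gaps = rng.uniform(0.3, 1.0, size=K)
    cum = np.cumsum(gaps)
    interior = cum[:-1] / cum[-1]  # K-1 points strictly inside (0, 1)
    lo, hi = spread
    return lo + (hi - lo) * interior


def generate_item_bank(spec: BankSpec | None = None, seed: int | None = None) -> ItemBank:
    """Build a synthetic bank matching the spec's structure and parameter profile.

    Slopes are drawn uniformly within the spec ranges; boundary locations
    are drawn as gap-constrained increasing difficulties on the spread
    range and converted to intercepts via ``d_k = -b_k * ||a||``.
    """
    spec = spec or BankSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    items: list[ItemParameters] = []
    for g, (name, count) in enumerate(spec.structure, start=1):
        K = spec.categories.get(name, 5)
        for j in range(count):
            a_gen = rng.uniform(*spec.a_general_range)
            a_grp = rng.uniform(*spec.a_group_range)
            b = _spread_difficulties(rng, K, spec.difficulty_spread)
            d = intercepts_from_difficulties(a_gen, a_grp, b)
            items.append(ItemParameters(
                item_id=f"{name}_{j + 1}", group_index=g,
                a_general=a_gen, a_group=a_grp, intercepts=d))
    for j in range(spec.n_general_only):
        a_gen = rng.uniform(*spec.a_general_range)
        b = _spread_difficulties(rng, GENERAL_ONLY_CATEGORIES, spec.difficulty_spread)
        d = intercepts_from_difficulties(a_gen, 0.0, b)
        items.append(ItemParameters(
            item_id=f"general_{j + 1}", group_index=0,
            a_general=a_gen, a_group=0.0, intercepts=d))
    return ItemBank(items=items, G=spec.G)


def simulate_responses(thetas: np.ndarray, bank: ItemBank, seed: int,
                       missing_rate: float = 0.0) -> np.ndarray:
    """Sample a complete (n, n_items) ordinal response matrix from the GRM.

    Each response is drawn from the item's category distribution at the
    person's true theta.  ``missing_rate`` > 0 blanks entries at random
    (marker -1), for exercising the full-information missing-data path of
    calibration; the default is a complete matrix.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 2 or thetas.shape[1] != bank.D:
        raise InvalidInputError(
            f"thetas must be (n, {bank.D}), got {thetas.shape}")
    if not 0.0 <= missing_rate < 1.0:
        raise InvalidInputError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = thetas.shape[0]
    z = thetas @ bank.loadings.T                       # (n, I)
    pstar = _boundary_probs(z, bank.padded_intercepts)  # (n, I, Kmax-1)
    probs = _cat_probs_from_boundary(pstar)             # (n, I, Kmax)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random((n, bank.n_items, 1))
    x = np.sum(u > cum[..., :-1], axis=-1).astype(int)
    x = np.minimum(x, bank.n_categories[None, :] - 1)
    if missing_rate > 0:
        mask = rng.random(x.shape) < missing_rate
        x = np.where(mask, -1, x)
    return x
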