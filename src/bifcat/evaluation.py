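"""Performance metrics for adaptive-testing simulations.

Summaries mirror the standard MCAT reporting columns: administered-item
counts (mean, median, interquartile range), item reduction relative to the
full bank, the general-factor SE at termination (mean and range), the
Pearson correlation between estimated and true traits, and the root mean
square difference

    RMSD = sqrt( sum_j (theta_hat_j - theta_j)^2 / N ).

A stopping SE threshold translates to classical reliability via
``reliability = 1 - SE^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import AdministrationRecord
from .grm import InvalidInputError, ItemBank

__all__ = [
    "rmsd", "pearson_correlation", "item_reduction", "se_to_reliability",
    "summarize_simulation", "summarize_design", "PerformanceSummary",
]


def rmsd(estimates, truths) -> float:
    """Root mean square difference between estimated and true trait values."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise InvalidInputError(f"conformable nonempty vectors required, got {est.shape} vs {tru.shape}")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


def pearson_correlation(estimates, truths) -> float:
    """Pearson correlation between estimated and true trait values."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size < 3:
        raise InvalidInputError("need equal-length vectors with >= 3 entries")
    if np.std(est) == 0 or np.std(tru) == 0:
        raise InvalidInputError("zero-variance input has no correlation")
    return float(np.corrcoef(est, tru)[0, 1])


def item_reduction(mean_items: float, bank_size: int) -> float:
    """Percent of the full-length instrument saved: 100 * (1 - mean / size)."""
    if not 0 < mean_items <= bank_size:
        raise InvalidInputError(
            f"mean_items must be in (0, {bank_size}], got {mean_items}")
    return 100.0 * (1.0 - mean_items / bank_size)


def se_to_reliability(se: float) -> float:
    """Classical reliability implied by a standard error: 1 - SE^2.

    Valid for SE in [0, 1] (trait variance fixed at 1); outside that range
    the conversion has no reliability interpretation.
    """
    if not 0.0 <= se <= 1.0:
        raise InvalidInputError(f"se must be in [0, 1], got {se}")
    return 1.0 - se**2


@dataclass
class PerformanceSummary:
    """Per-design-row performance: items, precision, and accuracy columns for one design row."""

    name: str
    n_respondents: int
    mean_items: float
    median_items: float
    iqr_items: tuple[float, float]
    item_reduction: float
    mean_se_general: float
    se_general_range: tuple[float, float]
    correlation: np.ndarray       # per dimension, theta_hat vs theta
    rmsd: np.ndarray              # per dimension
    mean_se_group: float          # across-group-factor mean of per-factor mean SE
    mean_correlation_group: float
    mean_rmsd_group: float

    @property
    def correlation_general(self) -> float:
        return float(self.correlation[0])

    @property
    def rmsd_general(self) -> float:
        return float(self.rmsd[0])


def summarize_simulation(records: list[AdministrationRecord], truths: np.ndarray,
                         bank: ItemBank, name: str = "") -> PerformanceSummary:
    """Aggregate one design row's administration records against the truth.

    SEs are taken at termination, per respondent.  The IQR is the 25th-75th
    percentile with linear interpolation.  Group-factor metrics are
    reported as the across-factor mean of per-factor values.
    """
    truths = np.asarray(truths, dtype=float)
    n = len(records)
    if n == 0 or truths.shape != (n, bank.D):
        raise InvalidInputError(
            f"records and truths must be conformable: {n} records, truths {truths.shape}")
    counts = np.array([r.n_items for r in records], dtype=float)
    est = np.array([r.theta_hat for r in records])
    se_gen = np.array([r.se[0] for r in records])
    def _corr(a, b):
        # degenerate dimensions (no spread in the estimates) -> NaN, not an error
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return pearson_correlation(a, b)

    corr = np.array([_corr(est[:, d], truths[:, d]) for d in range(bank.D)])
    rm = np.array([rmsd(est[:, d], truths[:, d]) for d in range(bank.D)])
    se_group_means = np.array([np.mean([r.se[d] for r in records])
                               for d in range(1, bank.D)])
    q25, q75 = np.percentile(counts, [25, 75])
    return PerformanceSummary(
        name=name,
        n_respondents=n,
        mean_items=float(np.mean(counts)),
        median_items=float(np.median(counts)),
        iqr_items=(float(q25), float(q75)),
        item_reduction=item_reduction(float(np.mean(counts)), bank.n_items),
        mean_se_general=float(np.mean(se_gen)),
        se_general_range=(float(np.min(se_gen)), float(np.max(se_gen))),
        correlation=corr,
        rmsd=rm,
        mean_se_group=float(np.mean(se_group_means)) if bank.G else float("nan"),
        mean_correlation_group=float(np.mean(corr[1:])) if bank.G else float("nan"),
        mean_rmsd_group=float(np.mean(rm[1:])) if bank.G else float("nan"),
    )


def summarize_design(results: dict[str, list[AdministrationRecord]],
                     truths: np.ndarray, bank: ItemBank,
                     relative_to: str | None = "full") -> pd.DataFrame:
    """One summary row per design row, as a DataFrame of the standard reporting columns.

    When ``relative_to`` names a row present in ``results``, delta columns
    (general-factor correlation/RMSD minus that row's values) are added.
    """
    summaries = {name: summarize_simulation(recs, truths, bank, name=name)
                 for name, recs in results.items()}
    rows = []
    base = summaries.get(relative_to) if relative_to else None
    for name, s in summaries.items():
        row = {
            "simulation": name,
            "mean_items": s.mean_items,
            "median_items": s.median_items,
            "iqr_low": s.iqr_items[0],
            "iqr_high": s.iqr_items[1],
            "item_reduction_pct": s.item_reduction,
            "mean_se_general": s.mean_se_general,
            "se_general_min": s.se_general_range[0],
            "se_general_max": s.se_general_range[1],
            "correlation_general": s.correlation_general,
            "rmsd_general": s.rmsd_general,
            "mean_se_group": s.mean_se_group,
            "mean_correlation_group": s.mean_correlation_group,
            "mean_rmsd_group": s.mean_rmsd_group,
        }
        if base is not None:
            row["d_correlation_vs_full"] = s.correlation_general - base.correlation_general
            row["d_rmsd_vs_full"] = s.rmsd_general - base.rmsd_general
        rows.append(row)
    return pd.DataFrame(rows)
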