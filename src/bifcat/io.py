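"""Readers and writers for the pipeline's text formats.

All tabular artifacts are comma-separated UTF-8 with "." decimals and an
empty cell as the missing marker.  Item banks additionally round-trip
through JSON.  Numeric cells are written at 12 significant digits so a
write-read round trip reproduces a bank exactly.
"""

from __future__ import annotations

import json
import sys
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .engine import AdministrationRecord, SimulationDesign, TerminationPolicy
from .grm import (
    InvalidInputError,
    ItemBank,
    ItemParameters,
    intercepts_from_difficulties,
)

__all__ = [
    "read_item_bank", "write_item_bank",
    "read_response_matrix", "write_response_matrix",
    "read_structure", "read_design", "write_design",
    "write_records", "write_summary", "write_manifest",
]

MAX_INTERCEPTS = 5  # supports K up to 6
_FMT = "%.12g"


def _fmt(v: float) -> str:
    return _FMT % v


def write_item_bank(bank: ItemBank, path) -> None:
    """Write a bank as CSV (or JSON when the path ends in .json)."""
    path = str(path)
    if path.endswith(".json"):
        payload = {
            "G": bank.G,
            "items": [
                {
                    "item_id": it.item_id,
                    "group_index": it.group_index,
                    "n_categories": it.n_categories,
                    "a_general": float(_fmt(it.a_general)),
                    "a_group": float(_fmt(it.a_group)),
                    "intercepts": [float(_fmt(d)) for d in it.intercepts],
                }
                for it in bank.items
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    cols = ["item_id", "group_index", "n_categories", "a_general", "a_group"]
    cols += [f"d{k}" for k in range(1, MAX_INTERCEPTS + 1)]
    lines = [",".join(cols)]
    for it in bank.items:
        cells = [it.item_id, str(it.group_index), str(it.n_categories),
                 _fmt(it.a_general), _fmt(it.a_group)]
        d = [_fmt(v) for v in it.intercepts]
        d += [""] * (MAX_INTERCEPTS - len(d))
        lines.append(",".join(cells + d))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_item_bank(path, dialect: str = "intercept") -> ItemBank:
    """Read a bank table (CSV or JSON).

    ``dialect="difficulty"`` interprets the d-columns as increasing
    difficulty thresholds b_k and converts them via d_k = -b_k * ||a||.
    Malformed rows are rejected with row-level diagnostics.
    """
    if dialect not in ("intercept", "difficulty"):
        raise InvalidInputError(f"unknown dialect {dialect!r}")
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        rows = [
            (it["item_id"], it["group_index"], it["n_categories"],
             it["a_general"], it["a_group"], list(map(float, it["intercepts"])))
            for it in payload["items"]
        ]
        G = int(payload["G"])
    else:
        df = pd.read_csv(path)
        rows = []
        for ridx, row in df.iterrows():
            K = int(row["n_categories"])
            d = []
            for k in range(1, K):
                cell = row.get(f"d{k}")
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise InvalidInputError(
                        f"{path} row {ridx}: missing intercept d{k} for K={K}")
                d.append(float(cell))
            rows.append((str(row["item_id"]), int(row["group_index"]), K,
                         float(row["a_general"]), float(row["a_group"]), d))
        G = max(r[1] for r in rows)
    items = []
    for ridx, (iid, g, K, a_gen, a_grp, d) in enumerate(rows):
        if len(d) != K - 1:
            raise InvalidInputError(
                f"{path} row {ridx}: expected {K - 1} thresholds, got {len(d)}")
        if dialect == "difficulty":
            d = intercepts_from_difficulties(a_gen, a_grp, d)
        try:
            items.append(ItemParameters(item_id=iid, group_index=g,
                                        a_general=a_gen, a_group=a_grp,
                                        intercepts=np.asarray(d, dtype=float)))
        except InvalidInputError as e:
            raise InvalidInputError(f"{path} row {ridx}: {e}") from e
    return ItemBank(items=items, G=G)


def write_response_matrix(x: np.ndarray, item_ids: list[str], path) -> None:
    """Write an ordinal response matrix; -1 entries become empty cells."""
    arr = np.asarray(x, dtype=float)
    arr = np.where(arr < 0, np.nan, arr)
    df = pd.DataFrame(arr, columns=item_ids)
    df.to_csv(path, index=False, float_format="%.0f")


def read_response_matrix(path, bank: ItemBank | None = None) -> pd.DataFrame:
    """Read a response matrix; validates categories against ``bank`` if given.

    The header must match the bank's item ids (a subset is allowed, with a
    warning on stderr).  Returns a DataFrame with NaN as missing marker.
    """
    df = pd.read_csv(path)
    if bank is not None:
        unknown = [c for c in df.columns if c not in bank.item_ids]
        if unknown:
            raise InvalidInputError(f"{path}: unknown item columns {unknown}")
        if len(df.columns) < bank.n_items:
            print(f"warning: {path} covers {len(df.columns)}/{bank.n_items} "
                  "bank items", file=sys.stderr)
        for c in df.columns:
            K = bank.n_categories[bank.index_of(c)]
            col = df[c].dropna()
            bad = col[(col < 0) | (col > K - 1)]
            if len(bad):
                j = bad.index[0]
                raise InvalidInputError(
                    f"{path}: response {bad.iloc[0]:g} out of range for item "
                    f"{c!r} (K={K}) at row {j}")
    return df


def read_structure(path) -> dict[str, int]:
    """Two-column CSV (item_id, group_index) -> mapping."""
    df = pd.read_csv(path)
    return {str(r["item_id"]): int(r["group_index"]) for _, r in df.iterrows()}


def write_design(design: SimulationDesign, path) -> None:
    rows = [{"name": r.name, "se_general": r.se_general, "se_group": r.se_group,
             "theta_change": r.theta_change, "max_items": r.max_items}
            for r in design]
    with open(path, "w") as fh:
        yaml.safe_dump({"rows": rows}, fh, sort_keys=False)


def read_design(path) -> SimulationDesign:
    """Read a stopping-rule design from YAML or JSON."""
    path = str(path)
    with open(path) as fh:
        payload = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    rows = [TerminationPolicy(
        name=str(r["name"]),
        se_general=r.get("se_general"),
        se_group=r.get("se_group"),
        theta_change=r.get("theta_change"),
        max_items=r.get("max_items"),
    ) for r in payload["rows"]]
    return SimulationDesign(rows=rows)


def write_records(results: dict[str, list[AdministrationRecord]], path,
                  trace_path=None) -> None:
    """One CSV row per respondent per design row; optional per-step trace."""
    rows = []
    for name, records in results.items():
        for r in records:
            row = {
                "simulation": name,
                "respondent": r.respondent,
                "n_items": r.n_items,
                "stop_reason": r.stop_reason,
                "items": "|".join(r.item_ids),
                "responses": "|".join(map(str, r.responses)),
            }
            for d, v in enumerate(r.theta_hat):
                row[f"theta_{d}"] = v
            for d, v in enumerate(r.se):
                row[f"se_{d}"] = v
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FMT)
    if trace_path is not None:
        trows = []
        for name, records in results.items():
            for r in records:
                for step, (iid, resp) in enumerate(zip(r.item_ids, r.responses)):
                    trow = {"simulation": name, "respondent": r.respondent,
                            "step": step + 1, "item_id": iid, "response": resp}
                    for d, v in enumerate(r.theta_history[step]):
                        trow[f"theta_{d}"] = v
                    trows.append(trow)
        pd.DataFrame(trows).to_csv(trace_path, index=False, float_format=_FMT)


def read_records(path) -> dict[str, list[AdministrationRecord]]:
    """Read an administration-records CSV back into record objects.

    Per-step trait histories are not stored in the records table; they
    come back empty, which is sufficient for performance summaries.
    """
    df = pd.read_csv(path)
    theta_cols = sorted((c for c in df.columns if c.startswith("theta_")),
                        key=lambda c: int(c.split("_")[1]))
    se_cols = sorted((c for c in df.columns if c.startswith("se_")),
                     key=lambda c: int(c.split("_")[1]))
    out: dict[str, list[AdministrationRecord]] = {}
    for _, row in df.iterrows():
        rec = AdministrationRecord(
            respondent=int(row["respondent"]),
            item_ids=str(row["items"]).split("|"),
            responses=[int(v) for v in str(row["responses"]).split("|")],
            theta_hat=row[theta_cols].to_numpy(dtype=float),
            se=row[se_cols].to_numpy(dtype=float),
            stop_reason=str(row["stop_reason"]),
            theta_history=np.empty((0, len(theta_cols))),
        )
        out.setdefault(str(row["simulation"]), []).append(rec)
    return out


def write_summary(summary: pd.DataFrame, path, json_path=None) -> None:
    summary.to_csv(path, index=False, float_format=_FMT)
    if json_path is not None:
        summary.to_json(json_path, orient="records", indent=1)


def write_manifest(path, config: dict) -> None:
    """Record config, seeds, and versions so artifacts are reproducible."""
    import bifcat
    manifest = {
        "bifcat_version": bifcat.__version__,
        "numpy_version": np.__version__,
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
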