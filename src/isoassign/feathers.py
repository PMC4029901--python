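"""Feather isotope tables: one record per individual bird.

The input is a CSV with columns ``id, group, maternal_species, year,
d2H, d13C, d15N`` (maternal_species and year optional).  Isotope fields
may be empty; missingness is tracked per isotope so a record can enter a
two-isotope analysis while being unusable for three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import ISOTOPE_ORDER

__all__ = ["FeatherRecord", "FeatherTableError", "read_feathers", "write_feathers"]


class FeatherTableError(ValueError):
    """Aggregated row-level parse errors, each tagged with its line number."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("feather table errors:\n  " + "\n  ".join(self.errors))


@dataclass(frozen=True)
class FeatherRecord:
    """One individual's isotope vector y* plus identity metadata."""

    id: str
    group: str
    values: dict[str, float | None] = field(default_factory=dict)
    maternal_species: str | None = None
    year: int | None = None

    def is_complete(self, isotopes: Iterable[str]) -> bool:
        return all(self.values.get(iso) is not None for iso in isotopes)

    def missing(self) -> tuple[str, ...]:
        return tuple(iso for iso in ISOTOPE_ORDER if self.values.get(iso) is None)

    def vector(self, isotopes: Sequence[str]) -> np.ndarray:
        """The measurement vector over ``isotopes``; raises if any is missing."""
        miss = [iso for iso in isotopes if self.values.get(iso) is None]
        if miss:
            raise ValueError(f"record {self.id!r} is missing isotope(s) {miss}")
        return np.array([self.values[iso] for iso in isotopes], dtype=float)


def read_feathers(
    path: str | Path, allowed_groups: Sequence[str] | None = None
) -> list[FeatherRecord]:
    """Parse a feather CSV into records, validating ids, groups and numbers.

    Errors are collected per row (with 1-based file line numbers, header =
    line 1) and raised together as :class:`FeatherTableError`.
    """
    df = pd.read_csv(path, dtype=str).rename(columns=lambda c: c.strip())
    required = {"id", "group"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FeatherTableError([f"missing required column(s): {sorted(missing_cols)}"])
    present_isos = [iso for iso in ISOTOPE_ORDER if iso in df.columns]
    if not present_isos:
        raise FeatherTableError(["no isotope columns found (expected any of d2H, d13C, d15N)"])

    errors: list[str] = []
    records: list[FeatherRecord] = []
    seen: dict[str, int] = {}
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        rid = (row["id"] or "").strip() if isinstance(row["id"], str) else row["id"]
        if not rid or pd.isna(rid):
            errors.append(f"line {line}: empty id")
            continue
        if rid in seen:
            errors.append(f"line {line}: duplicate id {rid!r} (first seen line {seen[rid]})")
            continue
        seen[rid] = line
        group = (row["group"] or "").strip() if isinstance(row["group"], str) else ""
        if not group:
            errors.append(f"line {line}: empty group for id {rid!r}")
            continue
        if allowed_groups is not None and group not in allowed_groups:
            errors.append(
                f"line {line}: unknown group {group!r} (allowed: {sorted(allowed_groups)})"
            )
            continue
        values: dict[str, float | None] = {}
        bad = False
        for iso in present_isos:
            raw = row[iso]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                values[iso] = None
                continue
            try:
                v = float(raw)
            except ValueError:
                errors.append(f"line {line}: non-numeric {iso} value {raw!r} for id {rid!r}")
                bad = True
                continue
            if not np.isfinite(v):
                errors.append(f"line {line}: non-finite {iso} value for id {rid!r}")
                bad = True
                continue
            values[iso] = v
        if bad:
            continue
        maternal = None
        if "maternal_species" in df.columns and isinstance(row["maternal_species"], str):
            maternal = row["maternal_species"].strip() or None
        year = None
        if "year" in df.columns and not pd.isna(row["year"]) and str(row["year"]).strip():
            try:
                year = int(float(row["year"]))
            except ValueError:
                errors.append(f"line {line}: non-numeric year {row['year']!r} for id {rid!r}")
                continue
        records.append(
            FeatherRecord(id=rid, group=group, values=values, maternal_species=maternal, year=year)
        )
    if errors:
        raise FeatherTableError(errors)
    return records


def write_feathers(records: Sequence[FeatherRecord], path: str | Path) -> Path:
    """Write records back to the CSV dialect read_feathers accepts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "group": r.group,
                "maternal_species": r.maternal_species or "",
                "year": r.year if r.year is not None else "",
                **{iso: ("" if r.values.get(iso) is None else r.values[iso]) for iso in ISOTOPE_ORDER},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
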