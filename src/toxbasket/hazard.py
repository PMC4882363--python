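"""GHS acute aquatic toxicity categories from 96-h fathead minnow LC50 data.

The UN Globally Harmonized System defines three acute categories by fish
LC50 band; a fourth catch-all covers everything above 100 mg/L:

====== ==================
CAT1   LC50 ≤ 1 mg/L
CAT2   1 < LC50 ≤ 10
CAT3   10 < LC50 ≤ 100
CAT4   LC50 > 100
====== ==================

The boundary value 1 mg/L is assigned to CAT1 (the conservative,
more-hazardous choice, matching official GHS usage of "≤ 1").
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "CATEGORIES",
    "HazardRecord",
    "ghs_category",
    "category_index",
    "read_hazard_csv",
    "write_hazard_csv",
]

CATEGORIES: tuple[str, ...] = ("CAT1", "CAT2", "CAT3", "CAT4")

# (upper bound inclusive, category); the last band is open-ended
_BANDS = ((1.0, "CAT1"), (10.0, "CAT2"), (100.0, "CAT3"), (math.inf, "CAT4"))

REQUIRED_COLUMNS = ("id", "smiles", "lc50_mg_per_L")


def ghs_category(lc50: float) -> str:
    """Discretize a 96-h fish LC50 (mg/L) into a GHS acute category."""
    if not math.isfinite(lc50) or lc50 <= 0:
        raise ValueError(f"LC50 must be a finite positive concentration, got {lc50!r}")
    for upper, cat in _BANDS:
        if lc50 <= upper:
            return cat
    raise AssertionError("unreachable")


def category_index(category: str) -> int:
    """0-based index of a category; lower index = more hazardous."""
    return CATEGORIES.index(category)


@dataclass(frozen=True)
class HazardRecord:
    """One chemical: id, structure, measured LC50, and its derived category."""

    id: str
    smiles: str
    lc50: float
    category: str = ""

    def __post_init__(self) -> None:
        derived = ghs_category(self.lc50)
        if self.category == "":
            object.__setattr__(self, "category", derived)
        elif self.category != derived:
            raise ValueError(
                f"chemical {self.id!r}: category {self.category} inconsistent "
                f"with LC50 {self.lc50} mg/L (expected {derived})"
            )


def read_hazard_csv(path: str | Path) -> list[HazardRecord]:
    """Read a hazard table CSV with header columns id, smiles, lc50_mg_per_L.

    Row order is preserved; duplicate ids, missing columns, and non-positive
    or non-numeric LC50 values raise ValueError naming the offending row.
    """
    records: list[HazardRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for rownum, row in enumerate(reader, start=2):
            cid = (row["id"] or "").strip()
            if not cid:
                raise ValueError(f"{path}: row {rownum}: empty chemical id")
            if cid in seen:
                raise ValueError(f"{path}: row {rownum}: duplicate id {cid!r}")
            seen.add(cid)
            try:
                lc50 = float(row["lc50_mg_per_L"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {rownum} (id {cid!r}): "
                    f"non-numeric LC50 {row['lc50_mg_per_L']!r}"
                ) from None
            try:
                records.append(HazardRecord(cid, (row["smiles"] or "").strip(), lc50))
            except ValueError as exc:
                raise ValueError(f"{path}: row {rownum} (id {cid!r}): {exc}") from None
    return records


def write_hazard_csv(records: list[HazardRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS + ("category",))
        for r in records:
            writer.writerow([r.id, r.smiles, repr(r.lc50), r.category])
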