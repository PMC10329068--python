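"""Graded-response-model item banks.

An item bank is an ordered collection of polytomous items, each with one
discrimination (slope) parameter ``a`` and ``m - 1`` ordered threshold
parameters ``b`` for ``m`` response categories.  Categories are coded
1..m, with higher categories indicating more of the latent trait (for the
bundled AAQ bank: more activity limitation, the "Not possible" option
being the highest category).

The bank bundled under :func:`aaq_bank` is the published graded-response
calibration of the 17-item Animated Activity Questionnaire, estimated on
1408 patients with hip/knee osteoarthritis with the latent trait scaled
to mean 0, SD 1 in that sample.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BankValidationError",
    "GradedItem",
    "ItemBank",
    "aaq_bank",
    "bank_summary",
    "collapse_categories",
    "load_bank",
    "validate_bank",
    "write_bank",
]


class BankValidationError(ValueError):
    """Raised when an item bank violates a structural invariant."""


@dataclass(frozen=True)
class GradedItem:
    """One graded-response item: slope ``a`` and ordered thresholds ``b``.

    ``b`` has length ``m - 1`` for ``m`` response categories.  A freshly
    category-collapsed item carries NaN thresholds and
    ``requires_recalibration=True`` until refitted.
    """

    id: str
    a: float
    b: tuple[float, ...]
    label: str = ""
    requires_recalibration: bool = False

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1

    def violations(self) -> list[str]:
        """Invariant violations of this item, as human-readable strings."""
        out: list[str] = []
        if not self.id:
            out.append("item has empty id")
        if not (self.a > 0) or not math.isfinite(self.a):
            out.append(f"item {self.id!r}: slope a={self.a} is not a positive finite number")
        if len(self.b) < 1:
            out.append(f"item {self.id!r}: fewer than 2 response categories")
        if self.requires_recalibration:
            return out  # thresholds are placeholders by design
        if any(not math.isfinite(t) for t in self.b):
            out.append(f"item {self.id!r}: non-finite threshold")
        elif any(self.b[k] >= self.b[k + 1] for k in range(len(self.b) - 1)):
            out.append(f"item {self.id!r}: thresholds not ascending: {self.b}")
        return out


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of :class:`GradedItem` with orientation metadata."""

    items: tuple[GradedItem, ...]
    orientation: str = "higher_theta_more_limitation"
    name: str = ""

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[GradedItem]:
        return iter(self.items)

    def __getitem__(self, key: int | str) -> GradedItem:
        if isinstance(key, str):
            for it in self.items:
                if it.id == key:
                    return it
            raise KeyError(key)
        return self.items[key]

    @property
    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def s_min(self) -> int:
        """Minimum possible summed score (all items at category 1)."""
        return len(self.items)

    @property
    def s_max(self) -> int:
        """Maximum possible summed score (all items at their top category)."""
        return sum(it.n_categories for it in self.items)

    def index(self, item_id: str) -> int:
        for i, it in enumerate(self.items):
            if it.id == item_id:
                return i
        raise KeyError(item_id)

    def subset(self, item_ids: Sequence[str]) -> "ItemBank":
        return ItemBank(tuple(self[i] for i in item_ids), self.orientation, self.name)


def validate_bank(bank: ItemBank) -> list[str]:
    """Report every invariant violation in *bank*; empty list means valid.

    Never raises: the report is the result.
    """
    out: list[str] = []
    if len(bank) == 0:
        return ["bank has no items"]
    seen: set[str] = set()
    for it in bank:
        if it.id in seen:
            out.append(f"duplicate item id {it.id!r}")
        seen.add(it.id)
        out.extend(it.violations())
    return out


def _require_valid(bank: ItemBank) -> ItemBank:
    problems = validate_bank(bank)
    if problems:
        raise BankValidationError("; ".join(problems))
    return bank


def _items_from_records(records: Iterable[Mapping]) -> tuple[GradedItem, ...]:
    items = []
    for rec in records:
        b = tuple(float(x) for x in rec["b"])
        items.append(
            GradedItem(
                id=str(rec["id"]),
                label=str(rec.get("label", "")),
                a=float(rec["a"]),
                b=b,
            )
        )
    return tuple(items)


def load_bank(source: str | Path | io.TextIOBase, fmt: str | None = None) -> ItemBank:
    """Load and validate an item bank from JSON or CSV.

    JSON is the canonical format: ``{"items": [{"id", "label", "a",
    "b": [...]}, ...], "orientation": ...}``.  CSV (one row per item,
    columns ``id,label,a,b1,b2,...``, trailing blanks for unused
    threshold slots) is accepted for spreadsheet-style entry.

    Raises :class:`BankValidationError` naming the offending item on
    non-positive slopes, non-ascending thresholds or duplicate ids.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if fmt is None:
            fmt = "csv" if path.suffix.lower() == ".csv" else "json"
    else:
        text = source.read()
        if fmt is None:
            fmt = "json" if text.lstrip().startswith("{") else "csv"

    if fmt == "json":
        doc = json.loads(text)
        items = _items_from_records(doc["items"])
        bank = ItemBank(
            items,
            orientation=doc.get("orientation", "higher_theta_more_limitation"),
            name=doc.get("name", ""),
        )
    elif fmt == "csv":
        reader = csv.DictReader(io.StringIO(text))
        records = []
        for row in reader:
            bcols = sorted(k for k in row if k and k.startswith("b") and k[1:].isdigit())
            b = [row[k] for k in sorted(bcols, key=lambda k: int(k[1:]))]
            b = [float(x) for x in b if x not in (None, "", "NA")]
            records.append({"id": row["id"], "label": row.get("label", ""), "a": row["a"], "b": b})
        bank = ItemBank(_items_from_records(records))
    else:
        raise ValueError(f"unknown bank format {fmt!r}")
    return _require_valid(bank)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write *bank* as canonical JSON, preserving full float precision."""
    doc = {
        "name": bank.name,
        "orientation": bank.orientation,
        "items": [
            {"id": it.id, "label": it.label, "a": it.a, "b": list(it.b)} for it in bank
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def aaq_bank() -> ItemBank:
    """The published 17-item AAQ graded-response parameter bank."""
    with resources.files("gradedcat.data").joinpath("aaq_bank.json").open("r") as fh:
        return load_bank(fh, fmt="json")


@dataclass(frozen=True)
class BankSummary:
    n_items: int
    slope_min: float
    slope_max: float
    threshold_min: float
    threshold_max: float
    category_counts: tuple[int, ...]
    s_min: int
    s_max: int


def bank_summary(bank: ItemBank) -> BankSummary:
    """Extrema and score-range summary of a valid bank."""
    _require_valid(bank)
    slopes = [it.a for it in bank]
    thresholds = [t for it in bank for t in it.b]
    return BankSummary(
        n_items=len(bank),
        slope_min=min(slopes),
        slope_max=max(slopes),
        threshold_min=min(thresholds),
        threshold_max=max(thresholds),
        category_counts=tuple(it.n_categories for it in bank),
        s_min=bank.s_min,
        s_max=bank.s_max,
    )


def collapse_categories(
    bank: ItemBank,
    responses: pd.DataFrame,
    item_id: str,
    merge_map: Mapping[int, int],
) -> tuple[ItemBank, pd.DataFrame]:
    """Merge response categories of one item and recode the data.

    *merge_map* maps each old category 1..m onto a new category 1..m',
    and must be onto a contiguous range and order-preserving (weakly
    increasing in the old category).  The returned bank carries a
    placeholder item with m'-1 NaN thresholds flagged
    ``requires_recalibration``; fitting new thresholds is the caller's
    job, mirroring the recalibrate-after-collapse workflow.
    """
    item = bank[item_id]
    old = sorted(merge_map)
    if old != list(range(1, item.n_categories + 1)):
        raise ValueError(
            f"merge map must cover categories 1..{item.n_categories} of {item_id!r}"
        )
    new = [merge_map[k] for k in old]
    if any(n2 < n1 for n1, n2 in zip(new, new[1:])):
        raise ValueError("merge map is not order-preserving")
    m_new = max(new)
    if sorted(set(new)) != list(range(1, m_new + 1)):
        raise ValueError("merge map is not onto a contiguous 1..m' range")

    if m_new == item.n_categories:  # identity map
        return bank, responses.copy()

    shell = replace(
        item, b=tuple([float("nan")] * (m_new - 1)), requires_recalibration=True
    )
    items = tuple(shell if it.id == item_id else it for it in bank)
    recoded = responses.copy()
    col = recoded[item_id]
    recoded[item_id] = col.map(lambda x: merge_map[int(x)] if pd.notna(x) else x)
    return ItemBank(items, bank.orientation, bank.name), recoded
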