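"""The 30-item skin-cancer risk item bank.

Each item in the bank is a polytomous survey question calibrated under the
Rasch partial credit model: an overall difficulty ``delta_i`` (logits) plus
up to four step thresholds ``tau_i1..tau_iK`` expressed as deviations from
the overall difficulty.  The effective threshold between adjacent score
categories ``k-1`` and ``k`` is ``delta_ik = delta_i + tau_ik``; an item
with ``K`` steps is scored ``0..K``.  A single-step item is dichotomous.

The packaged bank (``sccat/data/item_bank.csv``) holds the published
calibration of the 30-item skin-cancer risk questionnaire.  Step thresholds
in a centered parameterisation should sum to ~0 per item; several published
items deviate from this, so centering is reported by :func:`check_centering`
as a diagnostic rather than enforced at load time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "ItemBank",
    "ItemBankError",
    "load_item_bank",
    "write_item_bank",
    "packaged_bank",
    "check_centering",
]

#: columns of the item-bank CSV dialect, in order
CSV_COLUMNS = ["item_id", "text", "overall_difficulty", "step1", "step2", "step3", "step4"]

MAX_STEPS = 4


class ItemBankError(ValueError):
    """Raised for malformed item-bank files or invalid item parameters."""


@dataclass(frozen=True)
class ItemParameters:
    """Difficulty structure of one item.

    Parameters
    ----------
    item_id
        1-based identifier, unique within a bank.
    text
        Question wording.
    overall_difficulty
        Item difficulty ``delta_i`` in logits.
    step_thresholds
        Ordered step deviations ``tau_i1..tau_iK`` in logits, ``K`` in 1..4.
        A dichotomous item has a single step (conventionally 0.0).
    """

    item_id: int
    text: str
    overall_difficulty: float
    step_thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.step_thresholds:
            raise ItemBankError(f"item {self.item_id}: at least one step threshold required")
        if len(self.step_thresholds) > MAX_STEPS:
            raise ItemBankError(f"item {self.item_id}: more than {MAX_STEPS} steps")
        vals = [self.overall_difficulty, *self.step_thresholds]
        if not all(np.isfinite(vals)):
            raise ItemBankError(f"item {self.item_id}: non-finite difficulty value")

    @property
    def n_categories(self) -> int:
        """Number of score categories (``K + 1``, scored ``0..K``)."""
        return len(self.step_thresholds) + 1

    @property
    def max_score(self) -> int:
        return len(self.step_thresholds)

    @property
    def is_dichotomous(self) -> bool:
        return len(self.step_thresholds) == 1

    @property
    def category_thresholds(self) -> np.ndarray:
        """Effective thresholds ``delta_ik = delta_i + tau_ik`` (length K)."""
        return self.overall_difficulty + np.asarray(self.step_thresholds, dtype=float)


@dataclass
class ItemBank:
    """An ordered collection of :class:`ItemParameters`."""

    items: list[ItemParameters]
    name: str = "item_bank"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ItemBankError("duplicate item_ids in bank")
        if ids != list(range(1, len(ids) + 1)):
            raise ItemBankError("item_ids must be contiguous 1..N in order")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, item_id: int) -> ItemParameters:
        """Look up an item by its 1-based ``item_id``."""
        if not 1 <= item_id <= len(self.items):
            raise KeyError(f"item_id {item_id} not in bank of size {len(self.items)}")
        return self.items[item_id - 1]

    @property
    def max_scores(self) -> np.ndarray:
        """Top category of each item, in bank order."""
        return np.array([it.max_score for it in self.items])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItemBank):
            return NotImplemented
        return self.items == other.items


def check_centering(bank: ItemBank, tol: float = 0.05) -> dict[int, float]:
    """Report items whose step thresholds are not centered on zero.

    In the centered partial-credit parameterisation the step deviations of a
    polytomous item sum to zero and a dichotomous item's single step is zero.
    Returns ``{item_id: deviation}`` for items exceeding ``tol``.
    """
    out: dict[int, float] = {}
    for it in bank:
        dev = float(np.sum(it.step_thresholds))
        if abs(dev) > tol:
            out[it.item_id] = dev
    return out


def _bank_from_records(records: list[dict], name: str, metadata: dict | None) -> ItemBank:
    items = []
    for rec in records:
        steps = [s for s in rec["steps"] if s is not None]
        if any(s is None for s in rec["steps"][: len(steps)]):
            raise ItemBankError(f"item {rec['item_id']}: gap in step columns")
        items.append(
            ItemParameters(
                item_id=int(rec["item_id"]),
                text=str(rec["text"]),
                overall_difficulty=float(rec["overall"]),
                step_thresholds=tuple(float(s) for s in steps),
            )
        )
    return ItemBank(items=items, name=name, metadata=metadata or {})


def load_item_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Read an item bank from CSV or JSON.

    CSV dialect: header ``item_id,text,overall_difficulty,step1..step4``,
    ``NA`` (or an empty cell) marking absent steps — absent steps are
    dropped, never zero-filled.  JSON: object with ``name``, ``metadata``
    and an ``items`` array mirroring :class:`ItemParameters`.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        records = [
            {
                "item_id": it["item_id"],
                "text": it["text"],
                "overall": it["overall_difficulty"],
                "steps": list(it["step_thresholds"]),
            }
            for it in doc["items"]
        ]
        return _bank_from_records(records, doc.get("name", path.stem), doc.get("metadata"))
    if fmt != "csv":
        raise ItemBankError(f"unknown format {fmt!r} (expected 'csv' or 'json')")

    df = pd.read_csv(path, dtype={"text": str}, keep_default_na=True, na_values=["NA"])
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ItemBankError(f"item-bank CSV missing column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        steps = [getattr(row, f"step{j}") for j in range(1, MAX_STEPS + 1)]
        records.append(
            {
                "item_id": row.item_id,
                "text": row.text,
                "overall": row.overall_difficulty,
                "steps": [None if pd.isna(s) else float(s) for s in steps],
            }
        )
    return _bank_from_records(records, path.stem, {"source": str(path), "units": "logits"})


def write_item_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Write a bank so that :func:`load_item_bank` recovers an equal bank."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        doc = {
            "name": bank.name,
            "metadata": bank.metadata,
            "items": [
                {
                    "item_id": it.item_id,
                    "text": it.text,
                    "overall_difficulty": it.overall_difficulty,
                    "step_thresholds": list(it.step_thresholds),
                }
                for it in bank
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return
    if fmt != "csv":
        raise ItemBankError(f"unknown format {fmt!r} (expected 'csv' or 'json')")
    rows = []
    for it in bank:
        steps = list(it.step_thresholds) + [None] * (MAX_STEPS - len(it.step_thresholds))
        rows.append(
            {
                "item_id": it.item_id,
                "text": it.text,
                "overall_difficulty": it.overall_difficulty,
                **{f"step{j + 1}": s for j, s in enumerate(steps)},
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, na_rep="NA")


def packaged_bank(warn_on_centering: bool = False) -> ItemBank:
    """Load the packaged 30-item skin-cancer risk bank."""
    with resources.as_file(resources.files("sccat.data") / "item_bank.csv") as p:
        bank = load_item_bank(p)
    bank.name = "skin_cancer_30"
    bank.metadata = {"source": "packaged", "units": "logits"}
    if warn_on_centering:
        dev = check_centering(bank)
        if dev:
            warnings.warn(f"step thresholds not centered for items: {dev}", stacklevel=2)
    return bank
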