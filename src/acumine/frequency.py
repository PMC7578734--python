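"""Acupoint and meridian frequency tables.

Acupoint shares are expressed against the total number of usages (the sum
of all prescription sizes), the convention under which an acupoint used in
25 of 27 prescriptions carries a 19.2% share of 130 total usages rather
than a 92.6% share of prescriptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import pct
from .registry import Registry, TransactionDataset, ValidationError

#: Label under which extra-meridian experience points are reported.
EXTRA_MERIDIAN_LABEL = "extra"


@dataclass
class FrequencyTable:
    """Ranked frequency rows with percentage shares summing to ~100."""

    rows: pd.DataFrame  # columns: label, frequency, share_pct
    total: int

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def share_of(self, label: str) -> float:
        match = self.rows.loc[self.rows["label"] == label, "share_pct"]
        if match.empty:
            raise KeyError(label)
        return float(match.iloc[0])

    def frequency_of(self, label: str) -> int:
        match = self.rows.loc[self.rows["label"] == label, "frequency"]
        if match.empty:
            raise KeyError(label)
        return int(match.iloc[0])

    def write(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def _build_table(counts: dict[str, int], total: int, ndigits: int = 1) -> FrequencyTable:
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = pd.DataFrame(
        {
            "label": [k for k, _ in ordered],
            "frequency": [v for _, v in ordered],
            "share_pct": [pct(v, total, ndigits) for _, v in ordered],
        }
    )
    return FrequencyTable(rows=rows, total=total)


def acupoint_frequency(dataset: TransactionDataset) -> FrequencyTable:
    """Per-acupoint usage counts with shares of total usages.

    ``frequency(code)`` is the number of prescriptions containing the code;
    the share denominator is ``dataset.total_usages``.
    """
    if dataset.N == 0:
        raise ValidationError("empty dataset")
    counts = {code: dataset.item_count(code) for code in dataset.universe}
    return _build_table(counts, dataset.total_usages)


def meridian_frequency(
    dataset: TransactionDataset,
    registry: Registry,
    mode: str = "usage_sum",
) -> FrequencyTable:
    """Aggregate frequencies per meridian.

    ``usage_sum`` sums member-acupoint usage counts; ``prescription_count``
    counts prescriptions that use at least one acupoint of the meridian.
    Extra-meridian points are reported under :data:`EXTRA_MERIDIAN_LABEL`.
    Shares are relative to the table's own column total.
    """
    if mode not in ("usage_sum", "prescription_count"):
        raise ValueError(f"unknown meridian frequency mode {mode!r}")
    counts: dict[str, int] = {}
    if mode == "usage_sum":
        for code in dataset.universe:
            meridian = registry.meridian_of(code) or EXTRA_MERIDIAN_LABEL
            counts[meridian] = counts.get(meridian, 0) + dataset.item_count(code)
    else:
        for p in dataset.prescriptions:
            meridians = {
                registry.meridian_of(code) or EXTRA_MERIDIAN_LABEL
                for code in p.items
            }
            for meridian in meridians:
                counts[meridian] = counts.get(meridian, 0) + 1
    return _build_table(counts, sum(counts.values()))
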