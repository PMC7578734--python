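"""Domain vocabulary and transaction data model for acupoint prescriptions.

An acupoint prescription is the set of acupoints a single clinical trial
stimulated; a collection of prescriptions is a transaction dataset in the
market-basket sense.  This module defines the acupoint/meridian registry,
the :class:`Prescription` / :class:`TransactionDataset` containers, and the
long/wide file readers and writers everything downstream builds on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Meridian codes recognised for CSAP prescriptions.  Extra-meridian
#: "experience points" carry meridian ``None``.
MERIDIAN_CODES = ("PC", "LU", "HT", "ST", "BL", "RN", "LI", "LR", "SP", "KI")

_STANDARD_CODE_RE = re.compile(r"[A-Za-z]{1,3}\d{1,3}")


class RegistryError(KeyError):
    """Raised when an acupoint code cannot be resolved."""


class ValidationError(ValueError):
    """Raised on malformed transaction input."""


@dataclass(frozen=True)
class Acupoint:
    """A named stimulation site.

    ``meridian`` is one of :data:`MERIDIAN_CODES` or ``None`` for
    extra-meridian experience points.
    """

    code: str
    meridian: str | None = None
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.code or not self.code.strip():
            raise ValidationError("acupoint code must be non-empty")
        if self.meridian is not None and self.meridian not in MERIDIAN_CODES:
            raise ValidationError(
                f"unknown meridian {self.meridian!r} for acupoint {self.code!r}"
            )


def normalize_code(code: str) -> str:
    """Canonicalise an acupoint code: trim, and upper-case standard
    meridian+number codes.  Names that are not of that shape (experience
    points such as ``Xiongtong``) are kept verbatim after trimming."""
    code = code.strip()
    if _STANDARD_CODE_RE.fullmatch(code):
        return code.upper()
    return code


class Registry:
    """Case-insensitive acupoint lookup table.

    In strict mode unknown codes raise :class:`RegistryError`; in
    permissive mode they are auto-registered with meridian ``None`` and a
    warning, which lets the pipeline run on datasets beyond the built-in
    vocabulary.
    """

    def __init__(self, acupoints: Iterable[Acupoint] = (), strict: bool = True):
        self.strict = strict
        self._by_key: dict[str, Acupoint] = {}
        for point in acupoints:
            self.add(point)

    @staticmethod
    def _key(code: str) -> str:
        return code.strip().casefold()

    def add(self, point: Acupoint) -> None:
        key = self._key(point.code)
        if key in self._by_key:
            raise ValidationError(f"duplicate acupoint code {point.code!r}")
        self._by_key[key] = point

    def __contains__(self, code: str) -> bool:
        return self._key(code) in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def resolve(self, code: str) -> Acupoint:
        """Return the registered acupoint for ``code`` (case-insensitive,
        trimmed), auto-registering it when permissive."""
        key = self._key(code)
        point = self._by_key.get(key)
        if point is None:
            if self.strict:
                raise RegistryError(f"unknown acupoint code {code!r}")
            point = Acupoint(code=normalize_code(code), meridian=None)
            self._by_key[key] = point
            logger.warning("auto-registered unknown acupoint %r", point.code)
        return point

    def canonical(self, code: str) -> str:
        return self.resolve(code).code

    def meridian_of(self, code: str) -> str | None:
        return self.resolve(code).meridian


def load_registry(path: str | Path, strict: bool = True) -> Registry:
    """Read a registry file (columns ``code, meridian, display_name``)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    points = []
    for row in df.itertuples(index=False):
        meridian = row.meridian.strip() or None
        display = getattr(row, "display_name", "") or ""
        points.append(
            Acupoint(code=normalize_code(row.code), meridian=meridian,
                     display_name=display)
        )
    return Registry(points, strict=strict)


def builtin_registry(strict: bool = True) -> Registry:
    """The packaged 37-acupoint CSAP vocabulary (36 meridian points plus
    the Xiongtong experience point)."""
    with resources.as_file(
        resources.files("acumine.data").joinpath("registry.csv")
    ) as path:
        return load_registry(path, strict=strict)


def meridian_of(code: str, registry: Registry) -> str | None:
    """Meridian identifier for ``code``, or ``None`` for experience points."""
    return registry.meridian_of(code)


@dataclass(frozen=True)
class Prescription:
    """One trial's acupoint set (a transaction)."""

    study_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError(
                f"prescription {self.study_id!r} has no acupoints"
            )


@dataclass
class TransactionDataset:
    """An ordered list of prescriptions over a shared acupoint universe.

    The universe is ordered by descending prescription frequency with
    lexicographic tie-break, which makes every tabular output of the
    pipeline deterministic.
    """

    prescriptions: list[Prescription]
    universe: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.prescriptions:
            raise ValidationError("dataset must contain at least one prescription")
        counts: dict[str, int] = {}
        for p in self.prescriptions:
            for item in p.items:
                counts[item] = counts.get(item, 0) + 1
        self.universe = sorted(counts, key=lambda c: (-counts[c], c))
        self._counts = counts

    @property
    def N(self) -> int:
        return len(self.prescriptions)

    @property
    def total_usages(self) -> int:
        return sum(len(p.items) for p in self.prescriptions)

    def item_count(self, code: str) -> int:
        """Number of prescriptions containing ``code``."""
        return self._counts.get(code, 0)

    def joint_count(self, items: Iterable[str]) -> int:
        """Number of prescriptions containing every item of ``items``."""
        itemset = frozenset(items)
        return sum(1 for p in self.prescriptions if itemset <= p.items)

    def __len__(self) -> int:
        return self.N


def _canonicalise(code: str, registry: Registry | None) -> str:
    if registry is not None:
        return registry.canonical(code)
    return normalize_code(code)


def from_itemsets(
    records: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
    registry: Registry | None = None,
) -> TransactionDataset:
    """Build a dataset from ``{study_id: items}`` pairs."""
    pairs = records.items() if isinstance(records, Mapping) else records
    prescriptions = [
        Prescription(str(sid), frozenset(_canonicalise(c, registry) for c in items))
        for sid, items in pairs
    ]
    return TransactionDataset(prescriptions)


def load_transactions(
    path: str | Path,
    format: str = "long",
    registry: Registry | None = None,
) -> TransactionDataset:
    """Read prescriptions from a delimited text file.

    ``long`` format has one row per usage with columns
    ``study_id, acupoint``; ``wide`` format is a 0/1 incidence table with
    study identifiers in the first column and acupoint codes as headers.
    Duplicate (study, acupoint) rows collapse to a single set membership.
    """
    path = Path(path)
    if format == "long":
        df = pd.read_csv(path, dtype=str)
        if df.empty:
            raise ValidationError(f"no prescription rows in {path}")
        if df.shape[1] < 2:
            raise ValidationError(
                f"long format needs columns (study_id, acupoint); got {list(df.columns)}"
            )
        items: dict[str, set[str]] = {}
        pairs = zip(df.iloc[:, 0], df.iloc[:, 1])
        for idx, (sid, raw) in enumerate(pairs, start=2):
            sid = str(sid).strip()
            if not isinstance(raw, str) or not raw.strip():
                raise ValidationError(f"{path}: empty acupoint code at row {idx}")
            try:
                code = _canonicalise(raw, registry)
            except RegistryError as err:
                raise ValidationError(f"{path}: row {idx}: {err}") from err
            items.setdefault(sid, set()).add(code)
        return from_itemsets(list(items.items()))

    if format == "wide":
        df = pd.read_csv(path, index_col=0)
        if df.empty:
            raise ValidationError(f"no prescription rows in {path}")
        bad = ~df.isin([0, 1]).all(axis=None)
        if bad:
            raise ValidationError(f"{path}: wide-format cells must be 0 or 1")
        records = []
        for sid, row in df.iterrows():
            codes = [
                _canonicalise(str(col), registry)
                for col, val in row.items() if val == 1
            ]
            records.append((str(sid), codes))
        return from_itemsets(records)

    raise ValueError(f"unknown format {format!r}; expected 'long' or 'wide'")


def to_incidence_matrix(dataset: TransactionDataset) -> pd.DataFrame:
    """0/1 incidence matrix: one row per prescription, one column per
    universe item in universe order.  Row sums are prescription sizes and
    column sums are acupoint frequencies."""
    data = {
        code: [int(code in p.items) for p in dataset.prescriptions]
        for code in dataset.universe
    }
    index = [p.study_id for p in dataset.prescriptions]
    return pd.DataFrame(data, index=pd.Index(index, name="study_id"),
                        dtype=int)


def write_transactions(
    dataset: TransactionDataset, path: str | Path, format: str = "long"
) -> None:
    """Write a dataset back to long or wide delimited text."""
    path = Path(path)
    if format == "long":
        rows = [
            {"study_id": p.study_id, "acupoint": code}
            for p in dataset.prescriptions
            for code in sorted(p.items, key=dataset.universe.index)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "wide":
        to_incidence_matrix(dataset).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
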