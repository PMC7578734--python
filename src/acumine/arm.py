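"""Apriori frequent-itemset mining and association-rule generation.

Statistics follow the classic market-basket definitions over N
prescriptions: support s(A) = sigma(A)/N, confidence c(A -> b) =
sigma(A u {b}) / sigma(A), and lift = confidence / s(b); lift above 1
marks a positively associated pair.  All ratios are computed on exact
rationals and rounded half-up only for presentation.

Two support conventions are exposed for a rule A -> b:

``antecedent``
    support = sigma(A)/N, the convention of SPSS Modeler's Apriori node
    (a rule's printed support is its antecedent's support).
``joint``
    support = sigma(A u {b})/N, the textbook rule-support formula.

Rules always carry a single-item consequent.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, NamedTuple

from ._util import round_half_up
from .registry import TransactionDataset, ValidationError

SUPPORT_CONVENTIONS = ("antecedent", "joint")

#: Enumeration guard for the brute-force oracle.
BRUTE_FORCE_MAX_ITEMS = 20


@dataclass(frozen=True)
class Itemset:
    """A frequent itemset with its prescription count and support."""

    items: frozenset[str]
    count: int
    support_pct: float

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True, order=False)
class AssociationRule:
    """A mined rule ``antecedent -> consequent`` with its statistics.

    ``antecedent_count`` is sigma(antecedent) (the "Frequency" column of a
    Modeler-style rule table); ``joint_count`` is sigma(antecedent u
    {consequent}).  Percentages and lift are rounded half-up to 2 decimals.
    """

    antecedent: frozenset[str]
    consequent: str
    antecedent_count: int
    joint_count: int
    support_pct: float
    confidence_pct: float
    lift: float
    convention: str = "antecedent"

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | {self.consequent}

    def sort_key(self) -> tuple:
        return (
            len(self.antecedent),
            -self.support_pct,
            -self.confidence_pct,
            tuple(sorted(self.antecedent)),
            self.consequent,
        )


class RuleStats(NamedTuple):
    """Exact rational statistics for a candidate rule."""

    support_joint: Fraction
    support_antecedent: Fraction
    confidence: Fraction
    lift: Fraction


def _support_floor(min_support_pct: float, N: int) -> Fraction:
    return Fraction(str(min_support_pct))


def _meets(count: int, N: int, threshold_pct: Fraction) -> bool:
    return Fraction(count * 100, N) >= threshold_pct


def frequent_itemsets(
    dataset: TransactionDataset,
    min_support_pct: float = 15.0,
    max_size: int = 3,
) -> list[Itemset]:
    """Level-wise Apriori enumeration of itemsets with support at or above
    ``min_support_pct``, up to ``max_size`` items.

    Candidates of size k are joined from frequent (k-1)-itemsets and pruned
    when any (k-1)-subset is infrequent (downward closure), so only
    surviving candidates are counted against the data.
    """
    if dataset.N == 0:
        raise ValidationError("empty dataset")
    if not 0 < min_support_pct <= 100:
        raise ValueError("min_support_pct must be in (0, 100]")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")

    N = dataset.N
    floor = _support_floor(min_support_pct, N)
    transactions = [p.items for p in dataset.prescriptions]

    counts: dict[frozenset[str], int] = {}
    level = []
    for code in dataset.universe:
        c = dataset.item_count(code)
        if _meets(c, N, floor):
            s = frozenset([code])
            counts[s] = c
            level.append(s)

    frequent: list[frozenset[str]] = list(level)
    size = 1
    while level and size < max_size:
        size += 1
        prev = set(level)
        candidates = set()
        for a, b in combinations(level, 2):
            cand = a | b
            if len(cand) != size:
                continue
            if all(cand - {item} in prev for item in cand):
                candidates.add(cand)
        level = []
        for cand in candidates:
            c = sum(1 for t in transactions if cand <= t)
            if _meets(c, N, floor):
                counts[cand] = c
                level.append(cand)
        frequent.extend(level)

    result = [
        Itemset(items=s, count=counts[s],
                support_pct=round_half_up(Fraction(counts[s] * 100, N), 2))
        for s in frequent
    ]
    result.sort(key=lambda it: (len(it.items), -it.count, tuple(sorted(it.items))))
    return result


def rule_statistics(
    antecedent: Iterable[str], consequent: str, dataset: TransactionDataset
) -> RuleStats:
    """Exact support/confidence/lift for ``antecedent -> consequent``.

    Confidence is undefined (raises) when the antecedent never occurs.
    """
    A = frozenset(antecedent)
    if not A:
        raise ValueError("antecedent must be non-empty")
    if consequent in A:
        raise ValueError("consequent must not appear in the antecedent")
    N = dataset.N
    sigma_a = dataset.joint_count(A)
    if sigma_a == 0:
        raise ZeroDivisionError(
            f"confidence undefined: antecedent {sorted(A)} never occurs"
        )
    sigma_ab = dataset.joint_count(A | {consequent})
    sigma_b = dataset.item_count(consequent)
    confidence = Fraction(sigma_ab, sigma_a)
    support_b = Fraction(sigma_b, N)
    lift = confidence / support_b if sigma_b else Fraction(0)
    return RuleStats(
        support_joint=Fraction(sigma_ab, N),
        support_antecedent=Fraction(sigma_a, N),
        confidence=confidence,
        lift=lift,
    )


def _make_rule(
    A: frozenset[str],
    b: str,
    dataset: TransactionDataset,
    convention: str,
) -> AssociationRule:
    stats = rule_statistics(A, b, dataset)
    support = (
        stats.support_antecedent if convention == "antecedent"
        else stats.support_joint
    )
    sigma_a = dataset.joint_count(A)
    sigma_ab = dataset.joint_count(A | {b})
    return AssociationRule(
        antecedent=A,
        consequent=b,
        antecedent_count=sigma_a,
        joint_count=sigma_ab,
        support_pct=round_half_up(support * 100, 2),
        confidence_pct=round_half_up(stats.confidence * 100, 2),
        lift=round_half_up(stats.lift, 2),
        convention=convention,
    )


def generate_rules(
    itemsets: list[Itemset],
    dataset: TransactionDataset,
    min_confidence_pct: float = 80.0,
    support_convention: str = "antecedent",
    max_rule_size: int = 3,
) -> list[AssociationRule]:
    """Emit every rule A -> b with frequent antecedent A, single consequent
    b not in A, total size at most ``max_rule_size``, and confidence at or
    above ``min_confidence_pct``."""
    if support_convention not in SUPPORT_CONVENTIONS:
        raise ValueError(
            f"unknown support convention {support_convention!r}; "
            f"expected one of {SUPPORT_CONVENTIONS}"
        )
    if max_rule_size < 2:
        raise ValueError("max_rule_size must be >= 2")
    conf_floor = Fraction(str(min_confidence_pct))
    rules = []
    for itemset in itemsets:
        A = itemset.items
        if len(A) + 1 > max_rule_size:
            continue
        for b in dataset.universe:
            if b in A:
                continue
            sigma_ab = dataset.joint_count(A | {b})
            if Fraction(sigma_ab * 100, itemset.count) < conf_floor:
                continue
            rules.append(_make_rule(A, b, dataset, support_convention))
    rules.sort(key=AssociationRule.sort_key)
    return rules


def mine_rules(
    dataset: TransactionDataset,
    min_support_pct: float = 15.0,
    min_confidence_pct: float = 80.0,
    support_convention: str = "antecedent",
    max_rule_size: int = 3,
) -> list[AssociationRule]:
    """Convenience wrapper: frequent itemsets then rule generation."""
    itemsets = frequent_itemsets(
        dataset, min_support_pct=min_support_pct, max_size=max_rule_size - 1
    )
    return generate_rules(
        itemsets,
        dataset,
        min_confidence_pct=min_confidence_pct,
        support_convention=support_convention,
        max_rule_size=max_rule_size,
    )


def brute_force_rules(
    dataset: TransactionDataset,
    min_support_pct: float = 15.0,
    min_confidence_pct: float = 80.0,
    max_rule_size: int = 3,
    support_convention: str = "antecedent",
    allow_large: bool = False,
) -> list[AssociationRule]:
    """Exhaustive oracle: enumerate every antecedent subset and consequent
    directly, without level-wise pruning.  Guarded to small universes."""
    n_items = len(dataset.universe)
    if n_items > BRUTE_FORCE_MAX_ITEMS and not allow_large:
        raise ValueError(
            f"universe of {n_items} items exceeds the brute-force guard "
            f"({BRUTE_FORCE_MAX_ITEMS}); pass allow_large=True to override"
        )
    floor = _support_floor(min_support_pct, dataset.N)
    conf_floor = Fraction(str(min_confidence_pct))
    rules = []
    for size in range(1, max_rule_size):
        for combo in combinations(dataset.universe, size):
            A = frozenset(combo)
            sigma_a = dataset.joint_count(A)
            if sigma_a == 0 or not _meets(sigma_a, dataset.N, floor):
                continue
            for b in dataset.universe:
                if b in A:
                    continue
                sigma_ab = dataset.joint_count(A | {b})
                if Fraction(sigma_ab * 100, sigma_a) < conf_floor:
                    continue
                rules.append(_make_rule(A, b, dataset, support_convention))
    rules.sort(key=AssociationRule.sort_key)
    return rules


def rules_to_frame(rules: list[AssociationRule]):
    """Rule list as a Modeler-style table (acupoints, support, confidence,
    lift, antecedent frequency)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "antecedent": [", ".join(sorted(r.antecedent)) for r in rules],
            "consequent": [r.consequent for r in rules],
            "support_pct": [r.support_pct for r in rules],
            "confidence_pct": [r.confidence_pct for r in rules],
            "lift": [r.lift for r in rules],
            "frequency": [r.antecedent_count for r in rules],
        }
    )
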