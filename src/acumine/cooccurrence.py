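"""Pairwise acupoint co-occurrence counts across prescriptions.

The matrix is the Gram matrix of the 0/1 incidence matrix: entry (i, j)
counts the prescriptions containing both acupoints, and the diagonal
recovers single-acupoint frequencies.  Normalisation divides by the number
of prescriptions N, so 15 joint uses out of 27 prescriptions reads 55.6%.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_up
from .registry import TransactionDataset, to_incidence_matrix


@dataclass
class CooccurrenceMatrix:
    """Symmetric item-by-item joint prescription counts."""

    items: list[str]
    counts: pd.DataFrame  # square, integer, symmetric
    N: int

    @property
    def normalized(self) -> pd.DataFrame:
        """Counts as a percentage of N, half-up at 1 decimal."""
        vec = np.vectorize(
            lambda c: round_half_up(Fraction(int(c) * 100, self.N), 1)
        )
        return pd.DataFrame(
            vec(self.counts.to_numpy()),
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def count(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])

    def normalized_count(self, a: str, b: str) -> float:
        return round_half_up(Fraction(self.count(a, b) * 100, self.N), 1)

    def write(self, counts_path: str | Path, normalized_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path)
        if normalized_path is not None:
            self.normalized.to_csv(normalized_path)


def cooccurrence_matrix(dataset: TransactionDataset) -> CooccurrenceMatrix:
    """Joint prescription counts for every acupoint pair (Gram matrix of
    the incidence matrix)."""
    M = to_incidence_matrix(dataset).to_numpy()
    gram = M.T @ M
    df = pd.DataFrame(gram, index=dataset.universe, columns=dataset.universe,
                      dtype=int)
    return CooccurrenceMatrix(items=list(dataset.universe), counts=df,
                              N=dataset.N)


def top_pairs(
    matrix: CooccurrenceMatrix, k: int = 10, include_zero: bool = False
) -> list[tuple[str, str, int, float]]:
    """The k most frequent unordered acupoint pairs, ranked by joint count
    (descending) with lexicographic tie-break."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = []
    items = matrix.items
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = sorted((items[i], items[j]))
            c = matrix.count(a, b)
            if c == 0 and not include_zero:
                continue
            pairs.append((a, b, c, matrix.normalized_count(a, b)))
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return pairs[:k]
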