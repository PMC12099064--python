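"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import factorial
from typing import List, Sequence

import numpy as np
import pytest

from msipipe import MarkerDefinition, Panel, default_panel


@pytest.fixture(scope="session")
def panel() -> Panel:
    return default_panel()


@pytest.fixture()
def toy_marker() -> MarkerDefinition:
    return MarkerDefinition(
        name="TOY1",
        repeat_unit="A",
        ref_length=20,
        flank5="TACCGCTTGTTC",
        flank3="CTGTGGATTCGC",
    )


@pytest.fixture()
def toy_panel(toy_marker) -> Panel:
    second = MarkerDefinition(
        name="TOY2",
        repeat_unit="A",
        ref_length=15,
        flank5="GGATTCCATGCG",
        flank3="TTCGGACCACTG",
    )
    return Panel(markers=(toy_marker, second), version="toy")


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_fisher_rxc(table: Sequence[Sequence[int]]) -> Fraction:
    """Exact two-sided Fisher p as a rational number.

    Enumerates the first r-1 rows cell by cell (the last row is forced by
    the column margins) and sums exact multivariate-hypergeometric
    probabilities of every margin-matching table at most as probable as
    the observed one. Pure integer arithmetic throughout.
    """
    t = [list(map(int, row)) for row in table]
    row_sums = [sum(r) for r in t]
    col_sums = [sum(c) for c in zip(*t)]
    n = sum(row_sums)
    if n == 0 or min(len(t), len(t[0])) < 2:
        return Fraction(1)

    margin_num = 1
    for s in row_sums + col_sums:
        margin_num *= factorial(s)
    denom_base = factorial(n)

    def prob(cells: List[int]) -> Fraction:
        d = denom_base
        for c in cells:
            d *= factorial(c)
        return Fraction(margin_num, d)

    p_obs = prob([c for row in t for c in row])

    r, c = len(t), len(t[0])
    total = Fraction(0)

    def rows(i: int, cols_left: List[int], cells: List[int]) -> None:
        nonlocal total
        if i == r - 1:
            p = prob(cells + cols_left)
            if p <= p_obs:
                total += p
            return

        def fill(j: int, left: int, cols: List[int], row_cells: List[int]) -> None:
            if j == c - 1:
                if left <= cols[j]:
                    new_cols = cols.copy()
                    new_cols[j] -= left
                    rows(i + 1, new_cols, cells + row_cells + [left])
                return
            for v in range(min(left, cols[j]) + 1):
                new_cols = cols.copy()
                new_cols[j] -= v
                fill(j + 1, left - v, new_cols, row_cells + [v])

        fill(0, row_sums[i], cols_left, [])

    rows(0, col_sums.copy(), [])
    return total


def pairwise_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """O(n^2) ROC AUC: concordant pairs + half the tied pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_contingency_table(
    rng: np.random.Generator, max_n: int = 40
) -> np.ndarray:
    """Small random r x c table with positive margins for oracle checks."""
    r, c = rng.integers(2, 4, size=2)
    while True:
        n = int(rng.integers(4, max_n + 1))
        cells = rng.multinomial(n, np.ones(r * c) / (r * c)).reshape(r, c)
        if (cells.sum(axis=0) > 0).all() and (cells.sum(axis=1) > 0).all():
            return cells
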