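"""Nonparametric two-arm evaluation statistics.

The evaluation toolkit for a two-arm randomized comparison of search
interfaces: uncorrected Pearson chi-square on 2x2 frequency tables
(task completion / success counts per arm), the Mann-Whitney U test for
ordinal rating measures (exact enumeration for small samples, otherwise
a tie-corrected normal approximation), and a tabular summary of a
per-participant outcome table (counts with percentages for the binary
outcomes, mean and sample SD for each 1-7 rating measure).

Conventions, fixed deliberately:

* chi-square carries NO continuity (Yates) correction -- the statistic
  is n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with 1 df;
* all p values are two-sided;
* U is reported as min(U, n1*n2 - U);
* rating SDs use the n-1 denominator.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestMethod",
    "TestResult",
    "OutcomeSummary",
    "chi_square_2x2",
    "mann_whitney_u",
    "summarize_outcomes",
    "BINARY_OUTCOMES",
]

#: Binary outcome columns of the outcomes-table dialect, in report order.
BINARY_OUTCOMES = ("completed", "declared_found", "found_correct")


class TestMethod(str, enum.Enum):
    CHI_SQUARE_2x2 = "CHI_SQUARE_2x2"
    MANN_WHITNEY_U = "MANN_WHITNEY_U"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a,b; c,d): rows are arms, columns are outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name} must be a nonnegative integer")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: TestMethod

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def chi_square_2x2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table, 1 df, two-sided p.

    Raises ``ValueError`` when any margin is zero (statistic undefined).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: a table margin is zero")
    n = table.n
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=float(stat), p_value=p, method=TestMethod.CHI_SQUARE_2x2)


def _u_statistic(xs: Sequence[float], ys: Sequence[float]) -> float:
    """U1 = #{x > y} + 0.5 #{x = y}, computed via midranks."""
    n1, n2 = len(xs), len(ys)
    ranks = sps.rankdata(np.concatenate([xs, ys]))
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_p(xs: Sequence[float], ys: Sequence[float], u1_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled
    values to the two groups (valid with or without ties)."""
    pooled = list(xs) + list(ys)
    n1 = len(xs)
    total = 0
    le = 0
    ge = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u1 = _u_statistic(chosen, rest)
        total += 1
        if u1 <= u1_obs + 1e-9:
            le += 1
        if u1 >= u1_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def _normal_approx_p(
    xs: Sequence[float], ys: Sequence[float], u1: float
) -> float:
    """Two-sided p via the tie-corrected normal approximation with a
    0.5 continuity correction toward the mean."""
    n1, n2 = len(xs), len(ys)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([xs, ys])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    dev = abs(u1 - mu)
    z = max(0.0, dev - 0.5) / math.sqrt(var)
    return min(1.0, float(2.0 * sps.norm.sf(z)))


def mann_whitney_u(
    xs: Sequence[float], ys: Sequence[float], exact_max_n: int = 10
) -> TestResult:
    """Mann-Whitney U test: U = min(U1, n1*n2 - U1), two-sided p.

    The p value comes from exact enumeration of all group assignments
    when n1 + n2 <= ``exact_max_n``, otherwise from the tie-corrected
    normal approximation.  Raises ``ValueError`` on an empty sample.
    """
    xs = [float(v) for v in xs]
    ys = [float(v) for v in ys]
    if not xs or not ys:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(xs), len(ys)
    u1 = _u_statistic(xs, ys)
    u = min(u1, n1 * n2 - u1)
    if n1 + n2 <= exact_max_n:
        p = _exact_p(xs, ys, u1)
    else:
        p = _normal_approx_p(xs, ys, u1)
    return TestResult(statistic=float(u), p_value=p, method=TestMethod.MANN_WHITNEY_U)


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-arm tallies of a participant outcome table.

    ``counts[arm][outcome]`` is ``(count, denominator, percent)``;
    ``ratings[measure][arm]`` is ``(n, mean, sd)`` with mean/sd None when
    the arm contributed no values.
    """

    arms: tuple[str, ...]
    counts: Mapping[str, Mapping[str, tuple[int, int, float]]]
    ratings: Mapping[str, Mapping[str, tuple[int, float | None, float | None]]]


def summarize_outcomes(
    table: pd.DataFrame, arms: Sequence[str] = ("agent", "control")
) -> OutcomeSummary:
    """Tabulate a per-participant outcome table, one row per participant.

    Expects the outcomes-CSV dialect: an ``arm`` column, 0/1 columns for
    the binary outcomes present, and ``rating_*`` columns for 1-7
    measures.  Unknown arm labels raise ``ValueError``.
    """
    arms = tuple(arms)
    if "arm" not in table.columns:
        raise ValueError("outcome table must have an 'arm' column")
    unknown = set(table["arm"].unique()) - set(arms)
    if unknown:
        raise ValueError(f"unknown arm labels: {sorted(unknown)}")
    counts: dict[str, dict[str, tuple[int, int, float]]] = {}
    ratings: dict[str, dict[str, tuple[int, float | None, float | None]]] = {}
    rating_cols = [c for c in table.columns if c.startswith("rating_")]
    for arm in arms:
        sub = table[table["arm"] == arm]
        denom = len(sub)
        counts[arm] = {}
        for outcome in BINARY_OUTCOMES:
            if outcome not in table.columns:
                continue
            k = int(sub[outcome].sum()) if denom else 0
            pct = 100.0 * k / denom if denom else 0.0
            counts[arm][outcome] = (k, denom, pct)
    for col in rating_cols:
        measure = col[len("rating_") :]
        ratings[measure] = {}
        for arm in arms:
            vals = table.loc[table["arm"] == arm, col].dropna()
            if len(vals) == 0:
                ratings[measure][arm] = (0, None, None)
            else:
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                ratings[measure][arm] = (len(vals), float(vals.mean()), sd)
    return OutcomeSummary(arms=arms, counts=counts, ratings=ratings)
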