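"""Contingency-table arithmetic for cohort validation.

Utilities for the simple validation statistics used when comparing a
software-assisted shaping group against a manual-shaping group:
percentages from printed counts, the Pearson chi-squared test on 2x2
tables (no continuity correction), and Spearman rank correlation.
Continuous-outcome tests (t-test, Mann-Whitney) need per-patient data
and are deliberately not provided beyond these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwoTable",
    "proportion",
    "pearson_chi2",
    "spearman_rho",
    "two_by_two_from_csv",
    "summarize",
]


@dataclass
class TwoByTwoTable:
    """Group x outcome counts::

        group 1:  a (yes)   b (no)
        group 2:  c (yes)   d (no)
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
            setattr(self, name, int(v))

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError("numerator cannot exceed denominator")
    return round(100.0 * numerator / denominator, 2)


def pearson_chi2(table: TwoByTwoTable) -> tuple[float, float]:
    """Pearson chi-squared statistic and p-value on a 2x2 table,
    1 degree of freedom, without Yates continuity correction."""
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined with a zero marginal")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def two_by_two_from_csv(path) -> TwoByTwoTable:
    """Read a table from CSV with columns ``group,outcome_yes,outcome_no``
    (two rows, one per group)."""
    df = pd.read_csv(path)
    required = {"group", "outcome_yes", "outcome_no"}
    if not required.issubset(df.columns) or len(df) != 2:
        raise ValueError(
            "expected two rows with columns group,outcome_yes,outcome_no"
        )
    return TwoByTwoTable(
        int(df.outcome_yes.iloc[0]),
        int(df.outcome_no.iloc[0]),
        int(df.outcome_yes.iloc[1]),
        int(df.outcome_no.iloc[1]),
    )


def summarize(table: TwoByTwoTable, group_names=("group1", "group2")) -> pd.DataFrame:
    """Per-group outcome percentages and the chi-squared comparison."""
    stat, p = pearson_chi2(table)
    n1, n2 = table.a + table.b, table.c + table.d
    return pd.DataFrame(
        {
            "group": list(group_names),
            "n": [n1, n2],
            "outcome_yes": [table.a, table.c],
            "percent": [proportion(table.a, n1), proportion(table.c, n2)],
            "chi2": [stat] * 2,
            "p_value": [p] * 2,
        }
    )
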