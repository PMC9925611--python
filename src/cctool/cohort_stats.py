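"""Group-comparison descriptive statistics.

Welch's unequal-variance t-test recomputed from summary statistics (the
fractional Satterthwaite degrees of freedom are what published tables print),
the Pearson chi-square on a 2x2 contingency table without continuity
correction, and the Pearson correlation with its n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GroupSummary:
    """Mean, SD and n of one continuous trait in two groups."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def validate(self) -> None:
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("group SDs must be > 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")


def welch_t_from_summary(s: GroupSummary) -> tuple[float, float]:
    """Welch t statistic and Welch–Satterthwaite degrees of freedom.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2);
    df = (v1 + v2)^2 / (v1^2/(n1-1) + v2^2/(n2-1)) with vi = si^2/ni.
    """
    s.validate()
    v1 = s.sd1**2 / s.n1
    v2 = s.sd2**2 / s.n2
    t = (s.mean1 - s.mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    return float(t), float(df)


def welch_p(t: float, df: float) -> float:
    """Two-sided p-value for a Welch t statistic."""
    return float(2.0 * stats.t.sf(abs(t), df))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], no correction.

    Returns (statistic, df = 1, upper-tail p).  All margins must be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be > 0")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Sample Pearson correlation with df = n - 2 and its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), len(x) - 2, float(res.pvalue)
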