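"""Group-comparison statistics computable from printed summary data.

These reproduce demographic-table tests exactly from printed means, SDs and
counts: pooled-variance (Student) two-sample t-tests and the uncorrected
Pearson chi-square on a 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "pooled_ttest_from_summary", "chi2_2x2"]


@dataclass
class GroupSummary:
    """Mean, sample SD and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


def pooled_ttest_from_summary(
    a: GroupSummary, b: GroupSummary
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    sp^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2);
    t = (m_a - m_b) / (sp sqrt(1/n_a + 1/n_b)); df = n_a + n_b - 2;
    two-tailed p from Student's t.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    diff = a.mean - b.mean
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), df, p


def chi2_2x2(counts, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction by default.

    Returns (chi2, df=1, p).  Zero margins make the test undefined.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("counts must be a nonnegative 2x2 table")
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(c, correction=yates)
    return float(chi2), int(dof), float(p)
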