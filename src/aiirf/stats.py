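"""Population summaries and hypothesis tests for metric tables.

Summaries are reported as mean ± SEM; comparisons use two-tailed Student's
t tests (paired or unpaired, classical pooled-variance form by default with
a Welch option) and one-way ANOVA.  The numerical work defers to scipy;
this module adds the degenerate-input signalling and the df bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["GroupSummary", "TestResult", "mean_sem", "t_test", "one_way_anova"]


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined for the given data."""


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float
    values: list = field(default_factory=list)

    def __str__(self) -> str:  # "mean ± SEM (n)"
        return f"{self.mean:.3g} ± {self.sem:.2g} (n={self.n})"


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float
    p: float

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "df": self.df, "p": self.p}


def mean_sem(values: Sequence[float]) -> GroupSummary:
    """Sample mean and standard error (sd uses the n-1 denominator)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise DegenerateDataError("SEM requires at least two values")
    return GroupSummary(
        n=int(v.size),
        mean=float(v.mean()),
        sem=float(v.std(ddof=1) / np.sqrt(v.size)),
        values=v.tolist(),
    )


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> TestResult:
    """Two-tailed Student's t test.

    Unpaired tests use the classical pooled-variance form unless
    ``welch=True``; paired tests require equal n with matched ordering.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("t test requires n >= 2 per group")
    if paired:
        if a.size != b.size:
            raise DegenerateDataError("paired t test requires equal, matched n")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0) and np.allclose(d.mean(), 0.0):
            return TestResult("t_paired", 0.0, float(a.size - 1), 1.0)
        res = _sps.ttest_rel(a, b)
        return TestResult("t_paired", float(res.statistic), float(a.size - 1), float(res.pvalue))
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.allclose(a.mean(), b.mean()):
            return TestResult("t_unpaired", 0.0, float(a.size + b.size - 2), 1.0)
        raise DegenerateDataError("zero variance in both groups with unequal means")
    res = _sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(a.size + b.size - 2)
    name = "t_welch" if welch else "t_unpaired"
    return TestResult(name, float(res.statistic), df, float(res.pvalue))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA: between/within mean-square ratio, upper-tail p."""
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrs) < 2:
        raise DegenerateDataError("ANOVA requires at least two groups")
    if any(g.size < 2 for g in arrs):
        raise DegenerateDataError("ANOVA requires n >= 2 per group")
    pooled = np.concatenate(arrs)
    if np.allclose(pooled.std(ddof=0), 0.0):
        raise DegenerateDataError("F undefined: all observations identical")
    res = _sps.f_oneway(*arrs)
    df_between = float(len(arrs) - 1)
    df_within = float(pooled.size - len(arrs))
    r = TestResult("anova_oneway", float(res.statistic), df_between, float(res.pvalue))
    r.df_between, r.df_within = df_between, df_within  # type: ignore[attr-defined]
    return r
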