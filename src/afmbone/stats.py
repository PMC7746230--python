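"""Small statistical kernel: paired/unpaired t-tests and KS normality.

Every test returns a TestReport; degenerate (zero-variance) inputs
produce flagged reports instead of silent NaNs, which is reachable for
the small bone cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class TestReport:
    name: str
    statistic: float
    df: float
    pvalue: float
    alpha: float = ALPHA
    groups: List[Tuple[int, float, float]] = field(default_factory=list)
    degenerate: bool = False
    note: str = ""

    def __post_init__(self):
        if not self.degenerate and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha

    def to_text(self) -> str:
        lines = [f"{self.name}: statistic={self.statistic:.6g} df={self.df:.6g} "
                 f"p={self.pvalue:.6g} "
                 f"{'significant' if self.significant else 'not significant'} "
                 f"at alpha={self.alpha}"]
        for i, (n, m, sd) in enumerate(self.groups):
            lines.append(f"  group {i}: n={n} mean={m:.6g} sd={sd:.6g}")
        if self.degenerate:
            lines.append(f"  DEGENERATE: {self.note}")
        elif self.note:
            lines.append(f"  note: {self.note}")
        return "\n".join(lines)


def _summary(x: np.ndarray) -> Tuple[int, float, float]:
    return (int(x.size), float(x.mean()),
            float(x.std(ddof=1)) if x.size > 1 else 0.0)


def degenerate_report(name: str, note: str, groups=None) -> TestReport:
    return TestReport(name, statistic=0.0, df=0.0, pvalue=1.0,
                      groups=groups or [], degenerate=True, note=note)


def paired_t(x, y, name: str = "paired_t") -> TestReport:
    """Two-tailed paired t-test on the differences x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired samples need equal length >= 2")
    d = x - y
    groups = [_summary(x), _summary(y)]
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return TestReport(name, 0.0, float(x.size - 1), 1.0,
                              groups=groups, degenerate=True,
                              note="zero-variance, zero-mean differences")
        return TestReport(name, float(np.sign(d.mean()) * np.inf),
                          float(x.size - 1), 0.0, groups=groups,
                          degenerate=True,
                          note="zero-variance, non-zero differences")
    res = sps.ttest_rel(x, y)
    return TestReport(name, float(res.statistic), float(x.size - 1),
                      float(res.pvalue), groups=groups)


def unpaired_t(x, y, equal_variance: bool = True,
               name: str = "unpaired_t") -> TestReport:
    """Two-sided unpaired t-test (pooled-variance Student form by default)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    groups = [_summary(x), _summary(y)]
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestReport(name, 0.0, float(x.size + y.size - 2), 1.0,
                              groups=groups, degenerate=True,
                              note="both groups zero variance, equal means")
        return TestReport(name, float(np.sign(x.mean() - y.mean()) * np.inf),
                          float(x.size + y.size - 2), 0.0, groups=groups,
                          degenerate=True,
                          note="both groups zero variance, unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_variance)
    df = (x.size + y.size - 2) if equal_variance else float(res.df)
    return TestReport(name, float(res.statistic), float(df),
                      float(res.pvalue), groups=groups)


def ks_normality(x, name: str = "ks_normality") -> TestReport:
    """One-sample KS test against a normal with sample-estimated mean/SD.

    Uses the plain asymptotic KS p-value; because the parameters are
    estimated from the same sample the p-value is conservative (the
    report carries this caveat).
    """
    x = np.asarray(x, float)
    if x.size < 5:
        raise ValueError("KS normality check needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        return degenerate_report(name, "zero-variance sample",
                                 groups=[_summary(x)])
    res = sps.kstest(x, "norm", args=(x.mean(), sd), mode="asymp")
    return TestReport(name, float(res.statistic), float(x.size),
                      float(res.pvalue), groups=[_summary(x)],
                      note="normal parameters estimated from the sample; "
                           "asymptotic p is conservative")
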