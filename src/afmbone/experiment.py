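"""Condition-level aggregation and comparison for the force-spectroscopy arm.

Per environment (substrate x solution x pH x protein state) the pull
energies are summarized as mean +/- SE, normalized for display to a
reference environment (EDTA for films on mica, ultrapure water for
films on hydroxyapatite), and compared between conditions with a
KS normality check followed by a two-sided unpaired Student's t-test
at alpha 0.05.  Statistics always run on raw energies; normalization
is a display scaling only.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import DEFAULT_REFERENCE_MAP
from .core import PullMetrics, ValidationError
from . import stats

SUBSTRATES = ("mica", "HA")
SOLUTIONS = ("EDTA", "H2O", "Na", "Ca")
PH_LEVELS = (6.0, 7.4, 8.5)
OPN_STATES = ("native", "dephosphorylated")


@dataclass(frozen=True)
class Condition:
    substrate: str
    solution: str
    ph: float
    opn_state: str = "native"

    def __post_init__(self):
        if self.substrate not in SUBSTRATES:
            raise ValidationError(f"unknown substrate {self.substrate!r}")
        if self.solution not in SOLUTIONS:
            raise ValidationError(f"unknown solution {self.solution!r}")
        if self.opn_state not in OPN_STATES:
            raise ValidationError(f"unknown protein state {self.opn_state!r}")

    @property
    def key(self) -> str:
        return f"{self.substrate}/{self.solution}/pH{self.ph:g}/{self.opn_state}"

    @classmethod
    def from_key(cls, key: str) -> "Condition":
        try:
            substrate, solution, ph, state = key.split("/")
            return cls(substrate, solution, float(ph.removeprefix("pH")), state)
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"cannot parse condition key {key!r} "
                f"(expected substrate/solution/pH<x>/state)") from exc


@dataclass
class ConditionSummary:
    condition: Condition
    n: int
    mean: float                     # J
    sd: float                       # J
    se: float                       # J, sd / sqrt(n)
    n_rejected: int = 0
    normalized_mean: Optional[float] = None
    normalized_se: Optional[float] = None


def summarize_condition(metrics: Sequence[PullMetrics],
                        condition: Condition) -> ConditionSummary:
    """Mean, SD and SE of the energies over accepted pulls."""
    accepted = [m for m in metrics if not m.rejected]
    n_rejected = len(metrics) - len(accepted)
    if len(accepted) < 2:
        raise ValidationError(
            f"{condition.key}: need >= 2 accepted pulls, have {len(accepted)}")
    e = np.array([m.energy for m in accepted])
    sd = float(e.std(ddof=1))
    return ConditionSummary(condition, n=e.size, mean=float(e.mean()),
                            sd=sd, se=sd / math.sqrt(e.size),
                            n_rejected=n_rejected)


def normalize_to_reference(summaries: Sequence[ConditionSummary],
                           reference_map: Optional[Dict[str, str]] = None,
                           ) -> List[ConditionSummary]:
    """Divide each substrate group's means and SEs by the group's
    reference-condition mean; the reference normalizes to exactly 1.

    Operates on already-normalized values when present, which makes the
    operation idempotent (the reference's normalized mean is 1, so a
    second pass divides by 1).
    """
    ref_map = reference_map if reference_map is not None else DEFAULT_REFERENCE_MAP
    by_substrate: Dict[str, List[ConditionSummary]] = {}
    for s in summaries:
        by_substrate.setdefault(s.condition.substrate, []).append(s)
    ref_value: Dict[str, float] = {}
    for substrate, group in by_substrate.items():
        ref_solution = ref_map.get(substrate)
        if ref_solution is None:
            raise ValidationError(f"no reference solution declared for {substrate!r}")
        refs = [s for s in group if s.condition.solution == ref_solution]
        if not refs:
            raise ValidationError(
                f"reference condition ({substrate}/{ref_solution}) missing")
        if len(refs) > 1:
            raise ValidationError(
                f"ambiguous reference for {substrate!r}: {len(refs)} candidates")
        ref = refs[0]
        value = ref.normalized_mean if ref.normalized_mean is not None else ref.mean
        if value <= 0:
            raise ValidationError(
                f"reference mean for {substrate!r} must be positive")
        ref_value[substrate] = value
    out: List[ConditionSummary] = []
    for s in summaries:             # input order is preserved
        mean = s.normalized_mean if s.normalized_mean is not None else s.mean
        se = s.normalized_se if s.normalized_se is not None else s.se
        value = ref_value[s.condition.substrate]
        out.append(replace(s, normalized_mean=mean / value,
                           normalized_se=se / value))
    return out


@dataclass
class ComparisonReport:
    group_a: ConditionSummary
    group_b: ConditionSummary
    normality_a: stats.TestReport
    normality_b: stats.TestReport
    t_test: stats.TestReport

    @property
    def significant(self) -> bool:
        return self.t_test.significant

    def to_text(self) -> str:
        lines = [
            f"Comparison: {self.group_a.condition.key}  vs  "
            f"{self.group_b.condition.key}",
            f"  A: n={self.group_a.n} mean={self.group_a.mean:.6g} J "
            f"SE={self.group_a.se:.6g} J ({self.group_a.n_rejected} rejected)",
            f"  B: n={self.group_b.n} mean={self.group_b.mean:.6g} J "
            f"SE={self.group_b.se:.6g} J ({self.group_b.n_rejected} rejected)",
            self.normality_a.to_text(),
            self.normality_b.to_text(),
            self.t_test.to_text(),
        ]
        return "\n".join(lines)


def compare_conditions(a: Sequence[PullMetrics], b: Sequence[PullMetrics],
                       condition_a: Condition, condition_b: Condition,
                       equal_variance: bool = True) -> ComparisonReport:
    """KS normality per group, then a two-sided unpaired Student's
    t-test on the raw (not normalized) energies, alpha 0.05.

    Non-normal groups are flagged, not gated.
    """
    ea = np.array([m.energy for m in a if not m.rejected])
    eb = np.array([m.energy for m in b if not m.rejected])
    if ea.size < 3 or eb.size < 3:
        raise ValidationError("each condition needs >= 3 accepted pulls")
    for name, e in (("A", ea), ("B", eb)):
        if e.std(ddof=1) == 0:
            raise ValidationError(f"group {name} has zero variance")
    return ComparisonReport(
        group_a=summarize_condition(list(a), condition_a),
        group_b=summarize_condition(list(b), condition_b),
        normality_a=stats.ks_normality(ea, name=f"ks[{condition_a.key}]"),
        normality_b=stats.ks_normality(eb, name=f"ks[{condition_b.key}]"),
        t_test=stats.unpaired_t(ea, eb, equal_variance=equal_variance,
                                name="energy_t"))
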