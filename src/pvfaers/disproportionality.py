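"""Disproportionality statistics: reporting odds ratio and information component.

All statistics are computed on a 2x2 contingency table of exposure x event
among reports, with the GLP-1RA monotherapy cohort as the default comparator
(an active-comparator design):

    ===============  =============  ==============
                      target event   other events
    ===============  =============  ==============
    target exposure        a               b
    comparator             c               d
    ===============  =============  ==============

The reporting odds ratio is ROR = ad/(bc) with a 95% CI from the log-normal
approximation, exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).  The
information component is the log2 observed-to-expected reporting ratio; the
default estimator shrinks observed and expected by 0.5 and takes the lower
bound IC025 from the 2.5% quantile of the gamma posterior
Gamma(a + 0.5, rate E + 0.5), a standard credibility-interval construction in
Bayesian signal detection.  A plain (unshrunk) estimator with a delta-method
spread is also provided.  A signal requires a >= 3 cases, ROR CI lower bound
> 1 and IC025 > 0, jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .cohorts import CohortAssignment, TermSet, classify_event
from .faers_io import Report

__all__ = [
    "ContingencyTable",
    "SignalEstimate",
    "UnmaskingSpec",
    "SubgroupResult",
    "PSYCHOTROPIC_UNMASKING",
    "ANTIDIABETIC_UNMASKING",
    "build_contingency",
    "compute_ror",
    "compute_ic",
    "estimate_signal",
    "evaluate_signal",
    "run_unmasking",
    "sex_subgroup_analysis",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-event counts; ``a`` is target exposure & target event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class SignalEstimate:
    """ROR and IC statistics for one exposure/event contrast."""

    table: ContingencyTable
    ror: float = math.nan
    ror_ci_low: float = math.nan
    ror_ci_high: float = math.nan
    ic: float = math.nan
    ic_sd: Optional[float] = None
    ic025: float = math.nan
    ic_method: str = "shrinkage"
    n_cases: int = 0
    estimable: bool = False
    is_signal: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def build_contingency(assignments: Mapping[str, CohortAssignment],
                      term_set_name: str,
                      target: str = "combination",
                      comparator: str = "glp1ra_only") -> ContingencyTable:
    """Count the 2x2 cells from cohort assignments.

    ``comparator`` may be an exposure label or ``"database"``, in which case
    every non-target report forms the background (whole-database comparator).
    """
    if target == comparator:
        raise ValueError("target and comparator cohorts must differ")
    a = b = c = d = 0
    for assignment in assignments.values():
        event = bool(assignment.event_flags.get(term_set_name))
        if assignment.exposure == target:
            if event:
                a += 1
            else:
                b += 1
        elif comparator == "database" or assignment.exposure == comparator:
            if event:
                c += 1
            else:
                d += 1
    if a + b == 0 or c + d == 0:
        raise ValueError("empty cohort: target and comparator must both be non-empty")
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------

def compute_ror(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """ROR = ad/(bc) with log-normal 95% CI.

    No continuity correction: any zero cell makes the estimate non-estimable
    (the signal criteria require a >= 3 cases regardless).
    """
    a, b, c, d = table.cells()
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan, False
    ror = (a * d) / (b * c)
    half_width = 1.96 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror,
            math.exp(math.log(ror) - half_width),
            math.exp(math.log(ror) + half_width),
            True)


# ---------------------------------------------------------------------------
# Information component
# ---------------------------------------------------------------------------

def compute_ic(table: ContingencyTable,
               method: str = "shrinkage") -> tuple[float, Optional[float], float]:
    """Information component and its lower bound IC025.

    ``shrinkage`` (default): IC = log2((a + 0.5)/(E + 0.5)) with
    E = (a+b)(a+c)/N; IC025 is the log2 of the 2.5% quantile of the
    Gamma(a + 0.5, rate E + 0.5) posterior of the observed/expected ratio.
    Returns ``(ic, None, ic025)``.

    ``plain``: IC = log2(a*N / ((a+c)(a+b))) requiring a > 0, with the
    delta-method spread sd = (1/ln 2) * sqrt(1/a) and IC025 = IC - 2*sd.
    Returns ``(ic, sd, ic025)``.
    """
    a, b, c, d = table.cells()
    n = table.n
    expected = (a + b) * (a + c) / n
    if method == "shrinkage":
        ic = math.log2((a + 0.5) / (expected + 0.5))
        q = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (expected + 0.5))
        return ic, None, math.log2(q)
    if method == "plain":
        if a == 0:
            raise ValueError("plain IC requires a > 0 (non-estimable)")
        if expected == 0:
            raise ValueError("plain IC requires a positive expected count")
        ic = math.log2(a * n / ((a + c) * (a + b)))
        sd = math.sqrt(1 / a) / math.log(2)
        return ic, sd, ic - 2 * sd
    raise ValueError(f"unknown IC method {method!r}; use 'shrinkage' or 'plain'")


# ---------------------------------------------------------------------------
# Signal evaluation
# ---------------------------------------------------------------------------

def evaluate_signal(estimate: SignalEstimate) -> bool:
    """True iff a >= 3, ROR CI lower bound > 1 and IC025 > 0, jointly."""
    return bool(estimate.estimable
                and estimate.n_cases >= 3
                and estimate.ror_ci_low > 1
                and estimate.ic025 > 0)


def estimate_signal(table: ContingencyTable,
                    ic_method: str = "shrinkage",
                    note: str = "") -> SignalEstimate:
    """Compute ROR, IC and the signal flag for one contingency table."""
    est = SignalEstimate(table=table, n_cases=table.a, ic_method=ic_method, note=note)
    est.ror, est.ror_ci_low, est.ror_ci_high, est.estimable = compute_ror(table)
    try:
        est.ic, est.ic_sd, est.ic025 = compute_ic(table, ic_method)
    except ValueError:
        est.estimable = False
    est.is_signal = evaluate_signal(est)
    return est


# ---------------------------------------------------------------------------
# Unmasking analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnmaskingSpec:
    """Exclusion rule: drop reports containing any drug of the listed classes
    (in any role by default) and re-estimate the signal on the remainder."""

    name: str
    excluded_classes: frozenset
    roles: frozenset = frozenset({"PS", "SS", "C", "I"})

    def __post_init__(self) -> None:
        if not self.excluded_classes:
            raise ValueError("excluded_classes must be non-empty")

    def excludes(self, report: Report) -> bool:
        return any(d.class_tag in self.excluded_classes and d.role in self.roles
                   for d in report.drugs)


#: Concomitant psychoactive medication (antidepressants, benzodiazepines,
#: antipsychotics, opioids, sedatives, GABAergics) — the canonical drug list
#: behind the class tag ships with :mod:`pvfaers.faers_io`.
PSYCHOTROPIC_UNMASKING = UnmaskingSpec("no_psychotropics", frozenset({"psychotropic"}))

#: Concomitant non-metformin antidiabetics (SGLT-2i, DPP-4i, TZD, AGI,
#: sulfonylureas, insulins).
ANTIDIABETIC_UNMASKING = UnmaskingSpec("no_other_antidiabetics",
                                       frozenset({"antidiabetic_other"}))


def run_unmasking(reports: Sequence[Report],
                  assignments: Mapping[str, CohortAssignment],
                  spec: UnmaskingSpec,
                  term_set_name: str,
                  target: str = "combination",
                  comparator: str = "glp1ra_only",
                  ic_method: str = "shrinkage") -> SignalEstimate:
    """Re-estimate a signal after excluding reports with masking co-medication."""
    kept_ids = {r.report_id for r in reports if not spec.excludes(r)}
    kept = {rid: a for rid, a in assignments.items() if rid in kept_ids}
    try:
        table = build_contingency(kept, term_set_name, target, comparator)
    except ValueError as exc:
        dummy = ContingencyTable(0, 1, 0, 1) if "empty cohort" in str(exc) else None
        if dummy is None:
            raise
        return SignalEstimate(table=dummy, estimable=False,
                              note=f"empty cohort after exclusion ({spec.name})")
    return estimate_signal(table, ic_method=ic_method, note=spec.name)


# ---------------------------------------------------------------------------
# Sex-stratified subgroups
# ---------------------------------------------------------------------------

@dataclass
class SubgroupResult:
    """Per-PT signal estimates within each sex stratum plus M/F ROR ratios."""

    estimates: pd.DataFrame          # long format: pt, sex, a..d, ror, ci, ...
    ratios: dict = field(default_factory=dict)   # pt -> ror_male/ror_female or None


def sex_subgroup_analysis(reports: Sequence[Report],
                          assignments: Mapping[str, CohortAssignment],
                          term_set: TermSet,
                          target: str = "combination",
                          comparator: str = "glp1ra_only",
                          ic_method: str = "shrinkage",
                          pts: Optional[Sequence[str]] = None) -> SubgroupResult:
    """Per-preferred-term RORs stratified by sex (Unknown sex excluded).

    The male/female ratio of RORs is reported per PT and is null whenever
    either stratum's estimate is non-estimable.
    """
    if pts is None:
        pts = sorted(term_set.preferred_terms)
    by_sex: dict[str, list[Report]] = {"F": [], "M": []}
    for r in reports:
        if r.sex in by_sex and assignments[r.report_id].exposure in (target, comparator):
            by_sex[r.sex].append(r)

    rows = []
    ror_by = {}
    for sex, stratum in by_sex.items():
        for pt in pts:
            pt_set = TermSet.from_terms(pt, [pt])
            a = b = c = d = 0
            for r in stratum:
                flag, _ = classify_event(r, pt_set)
                if assignments[r.report_id].exposure == target:
                    a, b = (a + 1, b) if flag else (a, b + 1)
                else:
                    c, d = (c + 1, d) if flag else (c, d + 1)
            if a + b + c + d == 0:
                est = SignalEstimate(table=ContingencyTable(0, 1, 0, 1),
                                     estimable=False, note="empty stratum")
                cells = (a, b, c, d)
            else:
                est = estimate_signal(ContingencyTable(a, b, c, d), ic_method)
                cells = est.table.cells()
            ror_by[(pt, sex)] = est.ror if est.estimable else None
            rows.append({
                "pt": pt, "sex": sex,
                "a": cells[0], "b": cells[1], "c": cells[2], "d": cells[3],
                "ror": est.ror, "ror_ci_low": est.ror_ci_low,
                "ror_ci_high": est.ror_ci_high,
                "ic": est.ic, "ic025": est.ic025,
                "estimable": est.estimable, "is_signal": est.is_signal,
            })

    ratios = {}
    for pt in pts:
        m, f = ror_by.get((pt, "M")), ror_by.get((pt, "F"))
        ratios[pt] = (m / f) if (m is not None and f is not None) else None
    return SubgroupResult(estimates=pd.DataFrame(rows), ratios=ratios)
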