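"""Exposure cohorting, SMQ event classification and descriptive comparisons.

Reports are partitioned into four mutually exclusive exposure cohorts —
GLP-1RA + metformin combination, GLP-1RA monotherapy, metformin monotherapy,
other — and flagged against two narrow standardised MedDRA query (SMQ) term
sets: depression excluding suicide/self-injury (12 preferred terms) and
suicide/self-injury (9 preferred terms).  Group comparisons follow the
pharmacoepidemiological convention of an uncorrected Pearson chi-squared test
when every expected cell count is at least 5, and a two-sided Fisher exact
test (probability-mass rule) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .faers_io import Report

__all__ = [
    "TermSet",
    "DEPRESSION_EX_SUICIDE",
    "SUICIDE_SELF_INJURY",
    "DEFAULT_TERM_SETS",
    "load_term_sets",
    "ExposureRule",
    "CohortAssignment",
    "EXPOSURE_LABELS",
    "classify_exposure",
    "classify_event",
    "assign_cohorts",
    "compare_groups",
    "build_descriptive_table",
]

EXPOSURE_LABELS = ("combination", "glp1ra_only", "metformin_only", "other")


# ---------------------------------------------------------------------------
# Term sets (narrow SMQ preferred-term lists)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermSet:
    """A named set of MedDRA preferred terms; matching is case-insensitive."""

    name: str
    preferred_terms: frozenset

    @classmethod
    def from_terms(cls, name: str, terms: Iterable[str]) -> "TermSet":
        return cls(name=name, preferred_terms=frozenset(t.strip().lower() for t in terms))

    def __contains__(self, pt: str) -> bool:
        return pt.strip().lower() in self.preferred_terms


DEPRESSION_EX_SUICIDE = TermSet.from_terms("depression_ex_suicide", [
    "adjustment disorder with depressed mood",
    "anhedonia",
    "decreased interest",
    "depressed mood",
    "depression",
    "depressive symptom",
    "discouragement",
    "feeling of despair",
    "feelings of worthlessness",
    "major depression",
    "mixed anxiety and depressive disorder",
    "perinatal depression",
])

SUICIDE_SELF_INJURY = TermSet.from_terms("suicide_self_injury", [
    "completed suicide",
    "depression suicidal",
    "intentional overdose",
    "intentional self-injury",
    "self-injurious ideation",
    "suicidal behavior",
    "suicidal ideation",
    "suicide attempt",
    "suicide threat",
])

DEFAULT_TERM_SETS = (DEPRESSION_EX_SUICIDE, SUICIDE_SELF_INJURY)


def load_term_sets(path: str | Path) -> list[TermSet]:
    """Load term sets from a two-column CSV (term_set, preferred_term)."""
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return [TermSet.from_terms(name, group["preferred_term"])
            for name, group in frame.groupby("term_set", sort=True)]


# ---------------------------------------------------------------------------
# Exposure classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureRule:
    """Role-code rules defining the combination and monotherapy cohorts.

    By default the target GLP-1RA must be the primary suspect (PS) while
    metformin counts as a partner in any role; both role sets are
    configurable since reporting practice varies.
    """

    target_class: str = "glp1ra"
    partner_class: str = "metformin"
    target_roles: frozenset = frozenset({"PS"})
    partner_roles: frozenset = frozenset({"PS", "SS", "C", "I"})

    def __post_init__(self) -> None:
        if not self.target_roles or not self.partner_roles:
            raise ValueError("role sets must be non-empty")


def classify_exposure(report: Report, rule: ExposureRule = ExposureRule()) -> str:
    """Assign one of the four mutually exclusive exposure labels."""
    if not report.drugs:
        raise ValueError(f"report {report.report_id} has no drug records")
    target_in_role = any(d.class_tag == rule.target_class and d.role in rule.target_roles
                         for d in report.drugs)
    target_any = any(d.class_tag == rule.target_class for d in report.drugs)
    partner_in_partner_role = any(
        d.class_tag == rule.partner_class and d.role in rule.partner_roles
        for d in report.drugs)
    partner_in_target_role = any(
        d.class_tag == rule.partner_class and d.role in rule.target_roles
        for d in report.drugs)
    partner_any = any(d.class_tag == rule.partner_class for d in report.drugs)

    if target_in_role and partner_in_partner_role:
        return "combination"
    if target_in_role and not partner_any:
        return "glp1ra_only"
    if partner_in_target_role and not target_any:
        return "metformin_only"
    return "other"


def classify_event(report: Report, terms: TermSet) -> tuple[bool, frozenset]:
    """Flag a report whose reactions contain >=1 preferred term of the set."""
    matched = frozenset(pt.strip().lower() for pt in report.reactions if pt in terms)
    return bool(matched), matched


@dataclass
class CohortAssignment:
    report_id: str
    exposure: str
    event_flags: dict = field(default_factory=dict)   # term-set name -> bool
    matched_pts: dict = field(default_factory=dict)   # term-set name -> frozenset


def assign_cohorts(reports: Sequence[Report],
                   rule: ExposureRule = ExposureRule(),
                   term_sets: Sequence[TermSet] = DEFAULT_TERM_SETS,
                   ) -> dict[str, CohortAssignment]:
    """Classify every report; returns a map report_id -> assignment."""
    assignments = {}
    for report in reports:
        flags, matched = {}, {}
        for terms in term_sets:
            flag, pts = classify_event(report, terms)
            flags[terms.name] = flag
            matched[terms.name] = pts
        assignments[report.report_id] = CohortAssignment(
            report_id=report.report_id,
            exposure=classify_exposure(report, rule),
            event_flags=flags,
            matched_pts=matched,
        )
    return assignments


# ---------------------------------------------------------------------------
# Group comparison: Pearson chi-squared / Fisher exact
# ---------------------------------------------------------------------------

def compare_groups(table: Sequence[Sequence[float]]) -> tuple[float, str]:
    """Two-sided p-value for a 2x2 table of counts.

    Uses uncorrected Pearson chi-squared when all four expected counts are
    >= 5, otherwise the two-sided Fisher exact test (sum of probabilities of
    tables no more likely than the observed one).  Returns ``(nan,
    "not_computable")`` when a margin is zero.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    rows, cols, n = arr.sum(axis=1), arr.sum(axis=0), arr.sum()
    if (rows == 0).any() or (cols == 0).any():
        return math.nan, "not_computable"
    expected = np.outer(rows, cols) / n
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return float(p), "pearson_chi2"
    p = stats.fisher_exact(arr.astype(int), alternative="two-sided").pvalue
    return float(p), "fisher_exact"


# ---------------------------------------------------------------------------
# Descriptive table (characteristics of the two event cohorts)
# ---------------------------------------------------------------------------

_WEIGHT_BANDS = ("<50 kg", "50-100 kg", ">100 kg", "Unknown")
_AGE_BANDS = ("<18", "18-64", ">64", "Unknown")
_SOURCES = ("CN", "HP", "MD", "PH", "OT", "Unknown")
_OUTCOME_ROWS = ("DE", "DS", "HO", "LT", "OT", "Missing")
_SERIOUS_CODES = ("DE", "DS", "HO", "LT", "OT")


def _weight_band(kg: Optional[float]) -> str:
    if kg is None:
        return "Unknown"
    if kg < 50:
        return "<50 kg"
    if kg <= 100:
        return "50-100 kg"
    return ">100 kg"


def _age_band(years: Optional[float]) -> str:
    if years is None:
        return "Unknown"
    if years < 18:
        return "<18"
    if years <= 64:
        return "18-64"
    return ">64"


def build_descriptive_table(assignments: Mapping[str, CohortAssignment],
                            reports: Sequence[Report],
                            term_set: TermSet,
                            target: str = "combination",
                            comparator: str = "glp1ra_only") -> pd.DataFrame:
    """Characteristics of the event cohorts, target vs comparator exposure.

    One row per (characteristic block, level) with counts and percentages of
    each cohort's full size (Unknown levels included in the denominator), and
    one comparison p-value per serious-outcome row (outcome present vs absent
    across the two cohorts).  Empty cohorts yield zero counts with p-values
    marked not computable.
    """
    by_id = {r.report_id: r for r in reports}
    cohorts: dict[str, list[Report]] = {target: [], comparator: []}
    for rid, assignment in assignments.items():
        if assignment.exposure in cohorts and assignment.event_flags.get(term_set.name):
            cohorts[assignment.exposure].append(by_id[rid])
    n_target, n_comp = len(cohorts[target]), len(cohorts[comparator])

    def counts(reports_, key, levels):
        tally = dict.fromkeys(levels, 0)
        for r in reports_:
            tally[key(r)] += 1
        return tally

    rows = []

    def emit_block(block, levels, key):
        t = counts(cohorts[target], key, levels)
        c = counts(cohorts[comparator], key, levels)
        for level in levels:
            if level == "<18" and t[level] == 0 and c[level] == 0:
                continue
            rows.append(_row(block, level, t[level], n_target, c[level], n_comp))

    def _row(block, level, a, na, b, nb, p=math.nan, test=""):
        return {
            "block": block, "level": level,
            f"{target}_n": a,
            f"{target}_pct": round(100.0 * a / na, 1) if na else math.nan,
            f"{comparator}_n": b,
            f"{comparator}_pct": round(100.0 * b / nb, 1) if nb else math.nan,
            "p_value": p, "test": test,
        }

    emit_block("sex", ("F", "M", "Unknown"), lambda r: r.sex)
    emit_block("weight", _WEIGHT_BANDS, lambda r: _weight_band(r.weight_kg))
    emit_block("age", _AGE_BANDS, lambda r: _age_band(r.age_years))
    emit_block("report_source", _SOURCES, lambda r: r.report_source)

    for code in _SERIOUS_CODES:
        a = sum(1 for r in cohorts[target] if code in r.outcomes)
        b = sum(1 for r in cohorts[comparator] if code in r.outcomes)
        if n_target and n_comp:
            p, test = compare_groups([[a, n_target - a], [b, n_comp - b]])
        else:
            p, test = math.nan, "not_computable"
        rows.append(_row("serious_outcome", code, a, n_target, b, n_comp, p, test))
    a_miss = sum(1 for r in cohorts[target]
                 if not (r.outcomes & set(_SERIOUS_CODES)))
    b_miss = sum(1 for r in cohorts[comparator]
                 if not (r.outcomes & set(_SERIOUS_CODES)))
    rows.append(_row("serious_outcome", "Missing", a_miss, n_target, b_miss, n_comp))

    return pd.DataFrame(rows)
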