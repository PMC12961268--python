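"""Reading, writing and cleaning of FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System distributes each quarter as a set of
'$'-delimited ASCII tables (DEMO, DRUG, REAC, THER, OUTC, RPSR) keyed by a
report identifier (``primaryid``) and a case identifier (``caseid``).  This
module parses and emits that dialect, normalizes verbatim drug names to
canonical ingredients via a synonym table, assembles per-report records, and
deduplicates cases with the keep-latest rule used in spontaneous-report
analyses.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FaersParseError",
    "QuarterBundle",
    "DrugRecord",
    "Report",
    "SynonymTable",
    "TABLE_COLUMNS",
    "DEFAULT_SYNONYMS",
    "DRUG_CLASS_TAGS",
    "read_quarter",
    "write_quarter",
    "read_dataset",
    "write_dataset",
    "normalize_drug_name",
    "parse_faers_date",
    "full_date",
    "age_to_years",
    "bundles_to_reports",
    "deduplicate",
]

DELIM = "$"

#: Column layout of each quarterly table (subset of the FAERS ASCII schema
#: sufficient for exposure/event/TTO analyses).
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "event_dt", "sex",
        "age", "age_cod", "wt", "wt_cod", "occp_cod",
    ],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
    "rpsr": ["primaryid", "caseid", "rpsr_cod"],
}

TABLE_NAMES = tuple(TABLE_COLUMNS)

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

_QUARTER_RE = re.compile(r"^\d{4}Q[1-4]$")


class FaersParseError(ValueError):
    """Malformed FAERS ASCII input (wrong field count, missing column...)."""


# ---------------------------------------------------------------------------
# Quarter bundles
# ---------------------------------------------------------------------------

@dataclass
class QuarterBundle:
    """One quarter's worth of '$'-delimited tables, as string DataFrames."""

    quarter: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame

    def __post_init__(self) -> None:
        if not _QUARTER_RE.match(self.quarter):
            raise ValueError(f"quarter label {self.quarter!r} does not match YYYYQ[1-4]")

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self) -> None:
        """Check referential integrity: every row's report ID exists in demo."""
        known = set(self.demo["primaryid"])
        for name in ("drug", "reac", "ther", "outc", "rpsr"):
            tab = self.table(name)
            orphans = set(tab["primaryid"]) - known
            if orphans:
                raise ValueError(
                    f"{name.upper()} rows reference report IDs missing from DEMO: "
                    f"{sorted(orphans)[:5]}"
                )


def _read_table(path: Path, name: str) -> pd.DataFrame:
    want = TABLE_COLUMNS[name]
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FaersParseError(f"{path}: empty file, expected a '$'-separated header")
    header = lines[0].split(DELIM)
    missing = [c for c in want if c not in header]
    if missing:
        raise FaersParseError(f"{path}: missing mandatory column(s) {missing}")
    nfields = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(DELIM)
        if len(fields) != nfields:
            raise FaersParseError(
                f"{path}: line {lineno} has {len(fields)} fields, header has {nfields}"
            )
        rows.append(fields)
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    return frame[want] if rows else pd.DataFrame(columns=want, dtype=str)


def _write_table(frame: pd.DataFrame, path: Path, name: str) -> None:
    cols = TABLE_COLUMNS[name]
    frame = frame.reindex(columns=cols).fillna("").astype(str)
    for col in cols:
        bad = frame[col].str.contains(re.escape(DELIM), regex=True)
        if bad.any():
            raise ValueError(
                f"{name.upper()} column {col!r} contains the '$' delimiter "
                f"(row {bad.idxmax()}); the FAERS dialect has no escaping"
            )
    out = [DELIM.join(cols)]
    out.extend(DELIM.join(row) for row in frame.itertuples(index=False, name=None))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_quarter(directory: str | Path, quarter: str) -> QuarterBundle:
    """Read a quarter's six ASCII tables from ``directory``.

    Files are named ``DEMO.txt`` ... ``RPSR.txt``.  Raises
    :class:`FaersParseError` on wrong field counts (naming the line) or a
    missing mandatory column.
    """
    directory = Path(directory)
    tables = {name: _read_table(directory / f"{name.upper()}.txt", name)
              for name in TABLE_NAMES}
    bundle = QuarterBundle(quarter=quarter, **tables)
    bundle.validate()
    return bundle


def write_quarter(bundle: QuarterBundle, directory: str | Path) -> list[Path]:
    """Write a bundle's six tables as '$'-delimited files with header line."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in TABLE_NAMES:
        path = directory / f"{name.upper()}.txt"
        _write_table(bundle.table(name), path, name)
        paths.append(path)
    return paths


def write_dataset(bundles: Sequence[QuarterBundle], directory: str | Path) -> None:
    """Write each quarter into ``directory/<quarter>/``."""
    directory = Path(directory)
    for bundle in bundles:
        write_quarter(bundle, directory / bundle.quarter)


def read_dataset(directory: str | Path,
                 quarters: Optional[Sequence[str]] = None) -> list[QuarterBundle]:
    """Read every quarter subdirectory (or only ``quarters``) under ``directory``."""
    directory = Path(directory)
    if quarters is None:
        quarters = sorted(p.name for p in directory.iterdir()
                          if p.is_dir() and _QUARTER_RE.match(p.name))
    return [read_quarter(directory / q, q) for q in quarters]


# ---------------------------------------------------------------------------
# Dates and demographics
# ---------------------------------------------------------------------------

def parse_faers_date(value: str | None) -> tuple[Optional[int], Optional[int], Optional[int]]:
    """Parse a FAERS date string into (year, month, day) with None for missing parts.

    FAERS dates are 4-digit (year), 6-digit (year+month) or 8-digit
    (year+month+day) strings; anything else parses as fully missing.
    """
    if value is None:
        return (None, None, None)
    s = str(value).strip()
    if not s.isdigit():
        return (None, None, None)
    if len(s) == 4:
        return (int(s), None, None)
    if len(s) == 6:
        return (int(s[:4]), int(s[4:6]), None)
    if len(s) == 8:
        return (int(s[:4]), int(s[4:6]), int(s[6:8]))
    return (None, None, None)


def full_date(value: str | None) -> Optional[_dt.date]:
    """Return a calendar date only when the string is a complete 8-digit date."""
    y, m, d = parse_faers_date(value)
    if y is None or m is None or d is None:
        return None
    try:
        return _dt.date(y, m, d)
    except ValueError:
        return None


_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.1775,
                "DY": 1 / 365.25, "HR": 1 / 8766.0}


def age_to_years(age: str | None, age_cod: str | None) -> Optional[float]:
    """Convert a FAERS age + unit code to years; unknown unit -> missing."""
    if age is None or str(age).strip() == "":
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    factor = _AGE_FACTORS.get((age_cod or "YR").strip().upper() or "YR")
    if factor is None:
        return None
    return value * factor


# ---------------------------------------------------------------------------
# Drug-name normalization
# ---------------------------------------------------------------------------

def _fold(name: str) -> str:
    return " ".join(name.upper().split())


#: Canonical ingredient -> class tag.  Classes drive exposure cohorting and
#: unmasking exclusions downstream.
DRUG_CLASS_TAGS: dict[str, str] = {
    # GLP-1 receptor agonists
    "semaglutide": "glp1ra", "loxenatide": "glp1ra", "dulaglutide": "glp1ra",
    "albiglutide": "glp1ra", "tirzepatide": "glp1ra", "liraglutide": "glp1ra",
    "lixisenatide": "glp1ra", "exenatide": "glp1ra",
    "metformin": "metformin",
    # psychoactive concomitants (antidepressants, benzodiazepines,
    # antipsychotics, opioids, sedatives, GABAergics)
    "fluoxetine": "psychotropic", "sertraline": "psychotropic",
    "escitalopram": "psychotropic", "venlafaxine": "psychotropic",
    "bupropion": "psychotropic", "alprazolam": "psychotropic",
    "diazepam": "psychotropic", "lorazepam": "psychotropic",
    "quetiapine": "psychotropic", "olanzapine": "psychotropic",
    "zolpidem": "psychotropic", "oxycodone": "psychotropic",
    "tramadol": "psychotropic", "gabapentin": "psychotropic",
    "pregabalin": "psychotropic",
    # other antidiabetics (SGLT-2i, DPP-4i, TZD, AGI, sulfonylureas, insulins)
    "sitagliptin": "antidiabetic_other", "saxagliptin": "antidiabetic_other",
    "linagliptin": "antidiabetic_other", "empagliflozin": "antidiabetic_other",
    "dapagliflozin": "antidiabetic_other", "canagliflozin": "antidiabetic_other",
    "pioglitazone": "antidiabetic_other", "rosiglitazone": "antidiabetic_other",
    "acarbose": "antidiabetic_other", "glimepiride": "antidiabetic_other",
    "glipizide": "antidiabetic_other", "glyburide": "antidiabetic_other",
    "insulin glargine": "antidiabetic_other", "insulin aspart": "antidiabetic_other",
}

_DEFAULT_SYNONYM_PAIRS: list[tuple[str, str]] = [
    # brand names and development codes for the eight GLP-1RAs
    ("OZEMPIC", "semaglutide"), ("WEGOVY", "semaglutide"),
    ("RYBELSUS", "semaglutide"), ("NN9535", "semaglutide"),
    ("MOUNJARO", "tirzepatide"), ("ZEPBOUND", "tirzepatide"),
    ("LY3298176", "tirzepatide"),
    ("VICTOZA", "liraglutide"), ("SAXENDA", "liraglutide"),
    ("NN2211", "liraglutide"),
    ("TRULICITY", "dulaglutide"), ("LY2189265", "dulaglutide"),
    ("BYETTA", "exenatide"), ("BYDUREON", "exenatide"), ("AC2993", "exenatide"),
    ("TANZEUM", "albiglutide"), ("EPERZAN", "albiglutide"),
    ("ADLYXIN", "lixisenatide"), ("LYXUMIA", "lixisenatide"),
    ("AVE0010", "lixisenatide"),
    ("PEX168", "loxenatide"), ("PEX-168", "loxenatide"),
    ("POLYETHYLENE GLYCOL LOXENATIDE", "loxenatide"),
    ("GLUCOPHAGE", "metformin"), ("FORTAMET", "metformin"),
    ("GLUMETZA", "metformin"), ("RIOMET", "metformin"),
    ("METFORMIN HCL", "metformin"), ("METFORMIN HYDROCHLORIDE", "metformin"),
]


@dataclass
class SynonymTable:
    """Case- and whitespace-insensitive map from verbatim drug string to
    canonical ingredient name."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "SynonymTable":
        table = cls()
        for canonical in DRUG_CLASS_TAGS:
            table.add(canonical, canonical)
        for verbatim, canonical in _DEFAULT_SYNONYM_PAIRS:
            table.add(verbatim, canonical)
        return table

    def add(self, verbatim: str, canonical: str) -> None:
        self.mapping[_fold(verbatim)] = canonical

    def merge_csv(self, path: str | Path) -> "SynonymTable":
        """Overlay a two-column CSV (verbatim, canonical) onto this table."""
        extra = pd.read_csv(path, header=None, names=["verbatim", "canonical"],
                            dtype=str, skipinitialspace=True)
        for verbatim, canonical in extra.itertuples(index=False):
            self.add(verbatim, canonical)
        return self

    def lookup(self, verbatim: str) -> tuple[str, bool]:
        key = _fold(verbatim)
        if key in self.mapping:
            return self.mapping[key], True
        return verbatim, False


def normalize_drug_name(verbatim: str, table: SynonymTable) -> tuple[str, bool]:
    """Map a verbatim drug string to its canonical ingredient.

    Returns ``(canonical, True)`` for a known synonym and
    ``(verbatim, False)`` otherwise; the map is total.  Empty input is an
    error.
    """
    if not verbatim or not verbatim.strip():
        raise ValueError("empty drug name")
    return table.lookup(verbatim)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugRecord:
    verbatim_name: str
    canonical_name: str
    class_tag: str
    role: str
    therapy_start_date: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"role {self.role!r} not one of {ROLE_CODES}")


@dataclass
class Report:
    """One (possibly not yet deduplicated) safety report."""

    report_id: str
    case_id: str
    receipt_date: str
    sex: str = "Unknown"
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    report_source: str = "Unknown"
    outcomes: frozenset = frozenset()
    drugs: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    event_date: Optional[str] = None


_SOURCE_CODES = {"CN", "HP", "MD", "PH", "OT"}


def bundles_to_reports(bundles: Iterable[QuarterBundle],
                       synonyms: Optional[SynonymTable] = None,
                       class_tags: Optional[Mapping[str, str]] = None) -> list[Report]:
    """Assemble per-report records from quarterly tables, normalizing drug
    names and demographics along the way."""
    synonyms = synonyms or SynonymTable.default()
    class_tags = class_tags or DRUG_CLASS_TAGS

    demo = pd.concat([b.demo for b in bundles], ignore_index=True)
    drug = pd.concat([b.drug for b in bundles], ignore_index=True)
    reac = pd.concat([b.reac for b in bundles], ignore_index=True)
    ther = pd.concat([b.ther for b in bundles], ignore_index=True)
    outc = pd.concat([b.outc for b in bundles], ignore_index=True)

    starts: dict[tuple[str, str], str] = {
        (pid, seq): start
        for pid, seq, start in ther[["primaryid", "dsg_drug_seq", "start_dt"]]
        .itertuples(index=False)
        if str(start).strip()
    }
    drugs_by_report: dict[str, list[DrugRecord]] = {}
    for pid, seq, role, name in drug[
            ["primaryid", "drug_seq", "role_cod", "drugname"]].itertuples(index=False):
        canonical, _ = synonyms.lookup(name) if name.strip() else (name, False)
        drugs_by_report.setdefault(pid, []).append(DrugRecord(
            verbatim_name=name,
            canonical_name=canonical,
            class_tag=class_tags.get(canonical, "other"),
            role=role,
            therapy_start_date=starts.get((pid, seq)),
        ))
    reac_by_report: dict[str, list[str]] = {}
    for pid, pt in reac[["primaryid", "pt"]].itertuples(index=False):
        reac_by_report.setdefault(pid, []).append(pt)
    outc_by_report: dict[str, set[str]] = {}
    for pid, code in outc[["primaryid", "outc_cod"]].itertuples(index=False):
        if code.strip():
            outc_by_report.setdefault(pid, set()).add(code)

    reports = []
    for row in demo.itertuples(index=False):
        sex = row.sex if row.sex in ("F", "M") else "Unknown"
        try:
            weight = float(row.wt) if str(row.wt).strip() else None
        except ValueError:
            weight = None
        source = row.occp_cod if row.occp_cod in _SOURCE_CODES else "Unknown"
        reports.append(Report(
            report_id=row.primaryid,
            case_id=row.caseid,
            receipt_date=row.fda_dt,
            sex=sex,
            age_years=age_to_years(row.age, row.age_cod),
            weight_kg=weight,
            report_source=source,
            outcomes=frozenset(outc_by_report.get(row.primaryid, set())),
            drugs=drugs_by_report.get(row.primaryid, []),
            reactions=reac_by_report.get(row.primaryid, []),
            event_date=row.event_dt if str(row.event_dt).strip() else None,
        ))
    return reports


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _dedup_sort_key(report: Report) -> tuple:
    # latest receipt date wins; ties broken by largest report_id
    # (numeric comparison when possible, else lexicographic)
    rid = report.report_id
    rid_key: tuple = (1, int(rid)) if rid.isdigit() else (0, rid)
    return (report.receipt_date, rid_key)


def deduplicate(reports: Sequence[Report]) -> list[Report]:
    """Keep one report per case: latest receipt date, ties by largest report ID.

    Output is ordered by case ID; the operation is idempotent and never
    increases the report count.
    """
    best: dict[str, Report] = {}
    for report in reports:
        current = best.get(report.case_id)
        if current is None or _dedup_sort_key(report) > _dedup_sort_key(current):
            best[report.case_id] = report
    return [best[cid] for cid in sorted(best)]
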