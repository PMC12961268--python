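"""Synthetic FAERS-like data with known ground truth.

Generates quarterly '$'-delimited report bundles that structurally mimic the
FDA Adverse Event Reporting System: case/report ID pairs with injectable
duplicate contamination, drug records with PS/SS/C/I role codes and verbatim
names (brand names and development codes included, so name normalization is
exercised), MedDRA-preferred-term-coded reactions, demographics with explicit
Unknown categories, serious-outcome codes, and therapy-start/event dates with
Weibull-distributed onset intervals and partial-date censoring.

Disproportionality is injected as a rate multiplier on a term set within an
exposure pattern; the implied 2x2 tables and odds ratios are recorded in a
:class:`GroundTruth` sidecar so every downstream stage can be tested against
known truth.  Default parameters mirror a GLP-1RA / metformin
pharmacovigilance study: cohort shares and background event rates chosen so
the combination-to-monotherapy report ratio and the depression and
suicide/self-injury reporting rates resemble the observed cohorts, and onset
distributions taken from published Weibull fits per exposure pattern.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle, TABLE_COLUMNS

__all__ = [
    "ConfigError",
    "DrugSpec",
    "SimConfig",
    "GroundTruth",
    "DEFAULT_DRUG_CATALOG",
    "generate_dataset",
    "inject_duplicates",
    "ground_truth_summary",
]

EXPOSURES = ("combination", "glp1ra_only", "metformin_only", "other")

_WINDOW_START = _dt.date(2014, 1, 1)
_WINDOW_END = _dt.date(2024, 9, 30)

#: Non-target reactions every report can carry (keeps reactions non-empty).
_OTHER_PTS = ("Nausea", "Headache", "Diarrhoea", "Vomiting", "Dizziness",
              "Fatigue", "Injection site pain", "Decreased appetite")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class DrugSpec:
    canonical: str
    synonyms: tuple
    class_tag: str


DEFAULT_DRUG_CATALOG: tuple[DrugSpec, ...] = (
    DrugSpec("semaglutide", ("OZEMPIC", "WEGOVY", "RYBELSUS"), "glp1ra"),
    DrugSpec("tirzepatide", ("MOUNJARO", "ZEPBOUND", "LY3298176"), "glp1ra"),
    DrugSpec("liraglutide", ("VICTOZA", "SAXENDA"), "glp1ra"),
    DrugSpec("dulaglutide", ("TRULICITY",), "glp1ra"),
    DrugSpec("exenatide", ("BYETTA", "BYDUREON"), "glp1ra"),
    DrugSpec("albiglutide", ("TANZEUM",), "glp1ra"),
    DrugSpec("lixisenatide", ("ADLYXIN",), "glp1ra"),
    DrugSpec("loxenatide", ("PEX168",), "glp1ra"),
    DrugSpec("metformin", ("GLUCOPHAGE", "METFORMIN HCL"), "metformin"),
    DrugSpec("sertraline", (), "psychotropic"),
    DrugSpec("alprazolam", (), "psychotropic"),
    DrugSpec("quetiapine", (), "psychotropic"),
    DrugSpec("zolpidem", (), "psychotropic"),
    DrugSpec("sitagliptin", (), "antidiabetic_other"),
    DrugSpec("empagliflozin", (), "antidiabetic_other"),
    DrugSpec("glimepiride", (), "antidiabetic_other"),
    DrugSpec("insulin glargine", (), "antidiabetic_other"),
    DrugSpec("atorvastatin", (), "other"),
    DrugSpec("lisinopril", (), "other"),
    DrugSpec("omeprazole", (), "other"),
    DrugSpec("levothyroxine", (), "other"),
)


def _default_exposure_mix() -> dict:
    # combination : glp1ra_only ratio ~ 0.064, matching the observed cohorts
    return {"combination": 0.05, "glp1ra_only": 0.78,
            "metformin_only": 0.07, "other": 0.10}


def _default_event_rates() -> dict:
    # monotherapy reporting rates: 550/40841 (depression), 475/40841 (suicide)
    return {"depression_ex_suicide": 0.0135, "suicide_self_injury": 0.0116}


def _default_injections() -> tuple:
    # combination-cohort rate ratios implied by 47/2634 and 104/2634
    return (("combination", "depression_ex_suicide", 1.3),
            ("combination", "suicide_self_injury", 3.4))


def _default_tto() -> dict:
    # published Weibull (scale days, shape) per exposure pattern
    return {"combination": (70.21, 0.81), "glp1ra_only": (79.63, 0.69),
            "metformin_only": (92.40, 0.47), "other": (79.63, 0.69)}


def _default_demographics() -> dict:
    return {
        "sex": {"F": 0.56, "M": 0.38, "Unknown": 0.06},
        "age": {"18-64": 0.55, ">64": 0.15, "Unknown": 0.30},
        "weight": {"<50": 0.01, "50-100": 0.27, ">100": 0.13, "Unknown": 0.59},
        "source": {"CN": 0.55, "HP": 0.11, "MD": 0.26, "PH": 0.04,
                   "OT": 0.02, "Unknown": 0.02},
    }


def _default_outcome_rates() -> dict:
    # one serious-outcome code per report, "missing" = no OUTC row
    return {
        "suicide_self_injury": {"DE": 0.12, "DS": 0.05, "HO": 0.07,
                                "LT": 0.15, "OT": 0.44, "missing": 0.17},
        "depression_ex_suicide": {"DE": 0.016, "DS": 0.06, "HO": 0.067,
                                  "LT": 0.08, "OT": 0.30, "missing": 0.477},
        "none": {"DE": 0.01, "DS": 0.01, "HO": 0.10, "LT": 0.02,
                 "OT": 0.30, "missing": 0.56},
    }


def _default_concomitants() -> dict:
    return {"psychotropic": 0.10, "antidiabetic_other": 0.15}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_reports: int = 20_000
    drug_catalog: tuple = DEFAULT_DRUG_CATALOG
    exposure_mix: dict = field(default_factory=_default_exposure_mix)
    background_event_rate: dict = field(default_factory=_default_event_rates)
    signal_injections: tuple = field(default_factory=_default_injections)
    tto_distributions: dict = field(default_factory=_default_tto)
    demographics: dict = field(default_factory=_default_demographics)
    outcome_rates: dict = field(default_factory=_default_outcome_rates)
    concomitant_rates: dict = field(default_factory=_default_concomitants)
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.10
    seed: int = 0

    def multiplier(self, exposure: str, term_set: str) -> float:
        for exp, ts, mult in self.signal_injections:
            if exp == exposure and ts == term_set:
                return float(mult)
        return 1.0

    def event_rate(self, exposure: str, term_set: str) -> float:
        return self.background_event_rate[term_set] * self.multiplier(exposure, term_set)

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be a positive integer")
        vectors = {"exposure_mix": self.exposure_mix}
        for key, probs in self.demographics.items():
            vectors[f"demographics.{key}"] = probs
        for key, probs in self.outcome_rates.items():
            vectors[f"outcome_rates.{key}"] = probs
        for name, probs in vectors.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"probability vector {name!r} sums to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"probability vector {name!r} has a negative entry")
        for exp, ts, mult in self.signal_injections:
            if mult < 0:
                raise ConfigError(f"signal_injections multiplier for ({exp}, {ts}) "
                                  "must be >= 0")
            if ts not in self.background_event_rate:
                raise ConfigError(f"signal_injections references unknown term set {ts!r}")
            if exp not in EXPOSURES:
                raise ConfigError(f"signal_injections references unknown exposure {exp!r}")
        for exp, ts in ((e, t) for e in self.exposure_mix
                        for t in self.background_event_rate):
            if not 0 <= self.event_rate(exp, ts) <= 1:
                raise ConfigError(f"event rate for ({exp}, {ts}) outside [0, 1]")
        for exp, (scale, shape) in self.tto_distributions.items():
            if scale <= 0 or shape <= 0:
                raise ConfigError(f"tto_distributions[{exp!r}] Weibull parameters "
                                  "must be strictly positive")
        if not 0 <= self.duplicate_rate < 1:
            raise ConfigError("duplicate_rate must be in [0, 1)")
        if not 0 <= self.partial_date_rate < 1:
            raise ConfigError("partial_date_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator actually injected, for downstream verification."""

    n_reports: int
    exposure_probs: dict
    rates: dict = field(default_factory=dict)        # (exposure, term_set) -> rate
    multipliers: dict = field(default_factory=dict)  # (exposure, term_set) -> mult
    duplicate_case_ids: list = field(default_factory=list)

    def expected_cells(self, exposure: str, term_set: str) -> tuple[float, float]:
        """Expected (event, non-event) counts in a cohort at n_reports."""
        p = self.exposure_probs[exposure]
        r = self.rates[(exposure, term_set)]
        return self.n_reports * p * r, self.n_reports * p * (1 - r)

    def expected_table(self, term_set: str, target: str = "combination",
                       comparator: str = "glp1ra_only") -> tuple[float, float, float, float]:
        a, b = self.expected_cells(target, term_set)
        c, d = self.expected_cells(comparator, term_set)
        return a, b, c, d

    def theoretical_odds_ratio(self, term_set: str, target: str = "combination",
                               comparator: str = "glp1ra_only") -> float:
        rt = self.rates[(target, term_set)]
        rc = self.rates[(comparator, term_set)]
        return (rt / (1 - rt)) / (rc / (1 - rc))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_reports": self.n_reports,
            "exposure_probs": self.exposure_probs,
            "rates": {f"{e}|{t}": r for (e, t), r in self.rates.items()},
            "multipliers": {f"{e}|{t}": m for (e, t), m in self.multipliers.items()},
            "duplicate_case_ids": self.duplicate_case_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def ground_truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """One row per (exposure, term set): injected rate and expected 2x2 cells."""
    rows = []
    for (exposure, term_set), rate in sorted(gt.rates.items()):
        events, non_events = gt.expected_cells(exposure, term_set)
        rows.append({
            "exposure": exposure, "term_set": term_set,
            "rate": rate, "multiplier": gt.multipliers[(exposure, term_set)],
            "expected_events": events, "expected_non_events": non_events,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _date_str(date: _dt.date) -> str:
    return date.strftime("%Y%m%d")


def _truncate_date(value: str, rng: np.random.Generator) -> str:
    # blank the day; 30% of the time also the month
    return value[:4] if rng.random() < 0.3 else value[:6]


def _quarter_of(date_str: str) -> str:
    year, month = int(date_str[:4]), int(date_str[4:6])
    return f"{year}Q{(month - 1) // 3 + 1}"


_RPSR_BY_SOURCE = {"CN": "CSM", "HP": "HP", "MD": "HP", "PH": "HP",
                   "OT": "HP", "Unknown": "OTH"}

# term-set PT spellings as they appear in reaction records (mixed case, to
# exercise case-insensitive matching downstream)
_TERM_SET_PTS = {
    "depression_ex_suicide": (
        "Adjustment disorder with depressed mood", "Anhedonia",
        "Decreased interest", "Depressed mood", "Depression",
        "Depressive symptom", "Discouragement", "Feeling of despair",
        "Feelings of worthlessness", "Major depression",
        "Mixed anxiety and depressive disorder", "Perinatal depression",
    ),
    "suicide_self_injury": (
        "Completed suicide", "Depression suicidal", "Intentional overdose",
        "Intentional self-injury", "Self-injurious ideation",
        "Suicidal behavior", "Suicidal ideation", "Suicide attempt",
        "Suicide threat",
    ),
}


def _pick_verbatim(spec: DrugSpec, rng: np.random.Generator) -> str:
    variants = (spec.canonical,) + spec.synonyms
    return variants[int(rng.integers(len(variants)))]


def generate_dataset(config: SimConfig) -> tuple[list[QuarterBundle], GroundTruth]:
    """Generate quarterly FAERS-style bundles plus their ground truth.

    Deterministic: the same config (including seed) yields identical tables.
    Every report carries at least one primary-suspect drug; therapy start
    precedes the event date whenever both are emitted complete.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    term_sets = sorted(config.background_event_rate)

    catalog_by_class: dict[str, list[DrugSpec]] = {}
    for spec in config.drug_catalog:
        catalog_by_class.setdefault(spec.class_tag, []).append(spec)
    for needed in ("glp1ra", "metformin"):
        if needed not in catalog_by_class:
            raise ConfigError(f"drug_catalog has no {needed!r} entry")

    exposures = list(config.exposure_mix)
    exposure_idx = rng.choice(len(exposures),
                              size=n, p=[config.exposure_mix[e] for e in exposures])
    exposure = np.array(exposures, dtype=object)[exposure_idx]

    # event flags per term set, with injected multipliers
    flags: dict[str, np.ndarray] = {}
    for ts in term_sets:
        rates = np.array([config.event_rate(e, ts) for e in exposure], dtype=float)
        flags[ts] = rng.random(n) < rates

    # dates: therapy start uniform over the window (leaving room for onset),
    # event = start + Weibull onset (>= 1 day), receipt = event + delay
    start_lo = _WINDOW_START.toordinal()
    start_hi = (_WINDOW_END - _dt.timedelta(days=120)).toordinal()
    start_ord = rng.integers(start_lo, start_hi + 1, size=n)
    tto = np.empty(n, dtype=int)
    for exp_label, (scale, shape) in config.tto_distributions.items():
        mask = exposure == exp_label
        if mask.any():
            draws = scale * rng.weibull(shape, size=int(mask.sum()))
            tto[mask] = np.maximum(1, np.rint(draws).astype(int))
    unhandled = ~np.isin(exposure, list(config.tto_distributions))
    if unhandled.any():
        raise ConfigError("tto_distributions missing exposure pattern(s): "
                          f"{sorted(set(exposure[unhandled]))}")
    event_ord = start_ord + tto
    receipt_ord = np.minimum(event_ord + rng.integers(0, 61, size=n),
                             _WINDOW_END.toordinal())
    receipt_ord = np.maximum(receipt_ord, event_ord)  # receipt never precedes event

    # demographics
    demo_cfg = config.demographics
    def _draw(cfg: Mapping[str, float]) -> np.ndarray:
        levels = list(cfg)
        idx = rng.choice(len(levels), size=n, p=[cfg[k] for k in levels])
        return np.array(levels, dtype=object)[idx]

    sex = _draw(demo_cfg["sex"])
    age_band = _draw(demo_cfg["age"])
    weight_band = _draw(demo_cfg["weight"])
    source = _draw(demo_cfg["source"])
    age_val = np.where(age_band == "18-64", rng.integers(18, 65, size=n),
                       rng.integers(65, 91, size=n))
    weight_draw = rng.random(n)
    weight_val = np.select(
        [weight_band == "<50", weight_band == "50-100", weight_band == ">100"],
        [40 + 10 * weight_draw, 50 + 50 * weight_draw, 100 + 60 * weight_draw],
        default=np.nan)

    # serious outcome (categorical per event class; suicide dominates)
    outcome_class = np.where(flags.get("suicide_self_injury", np.zeros(n, bool)),
                             "suicide_self_injury",
                             np.where(flags.get("depression_ex_suicide",
                                                np.zeros(n, bool)),
                                      "depression_ex_suicide", "none"))
    outcome_code = np.empty(n, dtype=object)
    for cls, probs in config.outcome_rates.items():
        mask = outcome_class == cls
        if mask.any():
            codes = list(probs)
            idx = rng.choice(len(codes), size=int(mask.sum()),
                             p=[probs[k] for k in codes])
            outcome_code[mask] = np.array(codes, dtype=object)[idx]
    outcome_code[outcome_code == None] = "missing"  # noqa: E711 - object array

    partial_start = rng.random(n) < config.partial_date_rate
    partial_event = rng.random(n) < config.partial_date_rate

    demo_rows, drug_rows, reac_rows, ther_rows, outc_rows, rpsr_rows = \
        [], [], [], [], [], []
    other_pt_idx = rng.integers(len(_OTHER_PTS), size=n)

    for i in range(n):
        pid = str(100_000_001 + i)
        cid = str(20_000_001 + i)
        start_s = _date_str(_dt.date.fromordinal(int(start_ord[i])))
        event_s = _date_str(_dt.date.fromordinal(int(event_ord[i])))
        receipt_s = _date_str(_dt.date.fromordinal(int(receipt_ord[i])))
        start_out = _truncate_date(start_s, rng) if partial_start[i] else start_s
        event_out = _truncate_date(event_s, rng) if partial_event[i] else event_s

        demo_rows.append((
            pid, cid, receipt_s, event_out,
            {"F": "F", "M": "M"}.get(sex[i], ""),
            "" if age_band[i] == "Unknown" else str(int(age_val[i])),
            "" if age_band[i] == "Unknown" else "YR",
            "" if weight_band[i] == "Unknown" else f"{weight_val[i]:.1f}",
            "" if weight_band[i] == "Unknown" else "KG",
            "" if source[i] == "Unknown" else source[i],
        ))

        # drugs: role PS on the suspect, partner/concomitants in role C
        seq = 1
        def add_drug(spec: DrugSpec, role: str, start: Optional[str]) -> None:
            nonlocal seq
            drug_rows.append((pid, cid, str(seq), role, _pick_verbatim(spec, rng)))
            if start is not None:
                ther_rows.append((pid, cid, str(seq), start))
            seq += 1

        exp = exposure[i]
        if exp in ("combination", "glp1ra_only"):
            glp1s = catalog_by_class["glp1ra"]
            add_drug(glp1s[int(rng.integers(len(glp1s)))], "PS", start_out)
            if exp == "combination":
                mets = catalog_by_class["metformin"]
                add_drug(mets[int(rng.integers(len(mets)))], "C", None)
        elif exp == "metformin_only":
            mets = catalog_by_class["metformin"]
            add_drug(mets[int(rng.integers(len(mets)))], "PS", start_out)
        else:
            others = catalog_by_class.get("other") or catalog_by_class["metformin"]
            add_drug(others[int(rng.integers(len(others)))], "PS", start_out)
        for cls, prob in config.concomitant_rates.items():
            if cls in catalog_by_class and rng.random() < prob:
                pool = catalog_by_class[cls]
                add_drug(pool[int(rng.integers(len(pool)))], "C", None)

        # reactions: injected term-set PTs plus one background PT
        for ts in term_sets:
            if flags[ts][i]:
                pts = _TERM_SET_PTS.get(ts)
                if pts is None:
                    reac_rows.append((pid, cid, ts))
                else:
                    reac_rows.append((pid, cid, pts[int(rng.integers(len(pts)))]))
        reac_rows.append((pid, cid, _OTHER_PTS[int(other_pt_idx[i])]))

        if outcome_code[i] != "missing":
            outc_rows.append((pid, cid, str(outcome_code[i])))
        rpsr_rows.append((pid, cid, _RPSR_BY_SOURCE[str(source[i])]))

    tables = {
        "demo": pd.DataFrame(demo_rows, columns=TABLE_COLUMNS["demo"]),
        "drug": pd.DataFrame(drug_rows, columns=TABLE_COLUMNS["drug"]),
        "reac": pd.DataFrame(reac_rows, columns=TABLE_COLUMNS["reac"]),
        "ther": pd.DataFrame(ther_rows, columns=TABLE_COLUMNS["ther"]),
        "outc": pd.DataFrame(outc_rows, columns=TABLE_COLUMNS["outc"]),
        "rpsr": pd.DataFrame(rpsr_rows, columns=TABLE_COLUMNS["rpsr"]),
    }

    gt = GroundTruth(n_reports=n, exposure_probs=dict(config.exposure_mix))
    for exp in exposures:
        for ts in term_sets:
            gt.rates[(exp, ts)] = config.event_rate(exp, ts)
            gt.multipliers[(exp, ts)] = config.multiplier(exp, ts)

    bundles = _split_quarters(tables)
    if config.duplicate_rate > 0:
        bundles, dup_ids = inject_duplicates(bundles, config.duplicate_rate,
                                             seed=config.seed + 1)
        gt.duplicate_case_ids = dup_ids
    return bundles, gt


def _split_quarters(tables: Mapping[str, pd.DataFrame]) -> list[QuarterBundle]:
    demo = tables["demo"]
    quarter = demo["fda_dt"].map(_quarter_of)
    bundles = []
    for q in sorted(quarter.unique()):
        pids = set(demo.loc[quarter == q, "primaryid"])
        parts = {name: frame[frame["primaryid"].isin(pids)].reset_index(drop=True)
                 for name, frame in tables.items()}
        bundles.append(QuarterBundle(quarter=q, **parts))
    return bundles


# ---------------------------------------------------------------------------
# Duplicate injection
# ---------------------------------------------------------------------------

def inject_duplicates(bundles: Sequence[QuarterBundle], rate: float,
                      seed: int = 0) -> tuple[list[QuarterBundle], list[str]]:
    """Contaminate bundles with near-copy reports sharing the case ID.

    Each duplicate gets a fresh (larger) report ID and a later receipt date —
    exercising the keep-latest deduplication rule — and stays in its source
    quarter's files, as late-arriving FAERS versions do.  Returns the new
    bundles and the list of duplicated case IDs; ``rate = 0`` returns the
    input unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError("duplicate rate must be in [0, 1)")
    if rate == 0:
        return list(bundles), []
    rng = np.random.default_rng(seed)

    all_demo = pd.concat([b.demo for b in bundles], ignore_index=True)
    n = len(all_demo)
    n_dup = int(round(rate * n))
    if n_dup == 0:
        return list(bundles), []
    chosen = np.sort(rng.choice(n, size=n_dup, replace=False))
    max_pid = max(int(p) for p in all_demo["primaryid"])

    dup_case_ids = []
    new_bundles = []
    chosen_pids = {all_demo.iloc[k]["primaryid"]: j for j, k in enumerate(chosen)}
    delays = rng.integers(1, 91, size=n_dup)

    for bundle in bundles:
        extra: dict[str, list] = {name: [] for name in TABLE_COLUMNS}
        for row in bundle.demo.itertuples(index=False):
            j = chosen_pids.get(row.primaryid)
            if j is None:
                continue
            new_pid = str(max_pid + j + 1)
            receipt = _dt.datetime.strptime(row.fda_dt, "%Y%m%d").date()
            new_receipt = _date_str(receipt + _dt.timedelta(days=int(delays[j])))
            new_row = row._replace(primaryid=new_pid, fda_dt=new_receipt)
            extra["demo"].append(new_row)
            dup_case_ids.append(row.caseid)
            for name in ("drug", "reac", "ther", "outc", "rpsr"):
                tab = bundle.table(name)
                for child in tab[tab["primaryid"] == row.primaryid].itertuples(index=False):
                    extra[name].append(child._replace(primaryid=new_pid))
        parts = {}
        for name in TABLE_COLUMNS:
            base = bundle.table(name)
            if extra[name]:
                add = pd.DataFrame(extra[name], columns=base.columns)
                parts[name] = pd.concat([base, add], ignore_index=True)
            else:
                parts[name] = base.copy()
        new_bundles.append(QuarterBundle(quarter=bundle.quarter, **parts))
    return new_bundles, sorted(dup_case_ids)
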