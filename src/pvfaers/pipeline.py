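"""Config-driven orchestration: simulate/ingest -> dedup -> cohorts -> signals -> TTO.

One structured YAML config drives the whole analysis; every run writes CSV/JSON
outputs plus a machine-readable manifest (config hash, seed, package version)
so any output row is traceable to the run that produced it.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohorts import (DEFAULT_TERM_SETS, ExposureRule, TermSet, assign_cohorts,
                      build_descriptive_table, load_term_sets)
from .disproportionality import (ANTIDIABETIC_UNMASKING, PSYCHOTROPIC_UNMASKING,
                                 build_contingency, estimate_signal,
                                 run_unmasking, sex_subgroup_analysis)
from .faers_io import (SynonymTable, bundles_to_reports, deduplicate,
                       read_dataset, write_dataset)
from .synthetic_faers import SimConfig, generate_dataset, ground_truth_summary
from .tto_weibull import (DegenerateSampleError, TTOSample, extract_tto,
                          fit_weibull, median_iqr, onset_histogram)

__all__ = ["RunConfig", "run_pipeline", "export_results", "PipelineError"]

log = logging.getLogger("pvfaers")

_DEFAULT_QUARTERS = ("2014Q1", "2024Q3")

_TARGET_CLASSES = {"combination": ("glp1ra",), "glp1ra_only": ("glp1ra",),
                   "metformin_only": ("metformin",), "other": ("other",)}


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name for context."""


@dataclass
class RunConfig:
    """Everything one analysis run needs, expressible as a YAML file."""

    input_dir: Optional[str] = None
    simulate: Optional[SimConfig] = None
    quarter_range: tuple = _DEFAULT_QUARTERS
    exposure_rule: ExposureRule = field(default_factory=ExposureRule)
    term_set_file: Optional[str] = None
    synonym_file: Optional[str] = None
    unmasking: tuple = (PSYCHOTROPIC_UNMASKING, ANTIDIABETIC_UNMASKING)
    ic_method: str = "shrinkage"
    comparator: str = "active"          # "active" or "database"
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        lo, hi = self.quarter_range
        if (int(lo[:4]), lo[5:]) > (int(hi[:4]), hi[5:]):
            raise ValueError(f"quarter range {lo}..{hi} is not well-ordered")
        if self.ic_method not in ("shrinkage", "plain"):
            raise ValueError(f"unknown ic_method {self.ic_method!r}")
        if self.comparator not in ("active", "database"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.input_dir is None and self.simulate is None:
            raise ValueError("config needs either input_dir or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            if "signal_injections" in sim:
                sim["signal_injections"] = tuple(tuple(t) for t in sim["signal_injections"])
            if "tto_distributions" in sim:
                sim["tto_distributions"] = {k: tuple(v) for k, v
                                            in sim["tto_distributions"].items()}
            raw["simulate"] = SimConfig(**sim)
        if "exposure_rule" in raw and isinstance(raw["exposure_rule"], dict):
            rule = dict(raw["exposure_rule"])
            for key in ("target_roles", "partner_roles"):
                if key in rule:
                    rule[key] = frozenset(rule[key])
            raw["exposure_rule"] = ExposureRule(**rule)
        if "quarter_range" in raw:
            raw["quarter_range"] = tuple(raw["quarter_range"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _quarters_in_range(quarters: Sequence[str], lo: str, hi: str) -> list[str]:
    def key(q): return (int(q[:4]), int(q[5:]))
    return [q for q in quarters if key(lo) <= key(q) <= key(hi)]


def _signal_row(term: str, pt: str, est) -> dict:
    a, b, c, d = est.table.cells()
    return {"term_set": term, "pt": pt, "a": a, "b": b, "c": c, "d": d,
            "ror": est.ror, "ror_ci_low": est.ror_ci_low,
            "ror_ci_high": est.ror_ci_high, "ic": est.ic, "ic025": est.ic025,
            "ic_method": est.ic_method, "n_cases": est.n_cases,
            "estimable": est.estimable, "is_signal": est.is_signal,
            "note": est.note}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory results and writes
    CSV/JSON outputs plus a run manifest under ``config.output_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    stage = "simulate/ingest"
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            bundles, gt = generate_dataset(sim)
            data_dir = out / "synthetic_data"
            write_dataset(bundles, data_dir)
            gt.to_json(out / "ground_truth.json")
            ground_truth_summary(gt).to_csv(out / "ground_truth_summary.csv",
                                            index=False)
            input_dir = data_dir
        else:
            input_dir = Path(config.input_dir)
        bundles = read_dataset(input_dir)
        quarters = _quarters_in_range([b.quarter for b in bundles],
                                      *config.quarter_range)
        if not quarters:
            raise ValueError("no quarters in the configured range "
                             f"{config.quarter_range}")
        bundles = [b for b in bundles if b.quarter in quarters]
        synonyms = SynonymTable.default()
        if config.synonym_file:
            synonyms.merge_csv(config.synonym_file)
        reports = bundles_to_reports(bundles, synonyms)
        log.info("ingest: %d quarters, %d reports", len(bundles), len(reports))

        stage = "deduplicate"
        n_raw = len(reports)
        reports = deduplicate(reports)
        log.info("dedup: %d -> %d reports (%d duplicates removed)",
                 n_raw, len(reports), n_raw - len(reports))

        stage = "cohorts"
        term_sets: Sequence[TermSet] = (load_term_sets(config.term_set_file)
                                        if config.term_set_file else DEFAULT_TERM_SETS)
        assignments = assign_cohorts(reports, config.exposure_rule, term_sets)
        cohort_sizes = pd.Series([a.exposure for a in assignments.values()]
                                 ).value_counts().to_dict()
        log.info("cohorts: %s", cohort_sizes)

        comparator = "glp1ra_only" if config.comparator == "active" else "database"

        stage = "descriptives"
        descriptives = {}
        for ts in term_sets:
            table = build_descriptive_table(assignments, reports, ts)
            table.to_csv(out / f"descriptive_{ts.name}.csv", index=False)
            descriptives[ts.name] = table

        stage = "signals"
        signal_rows = []
        for ts in term_sets:
            est = estimate_signal(
                build_contingency(assignments, ts.name, "combination", comparator),
                ic_method=config.ic_method)
            signal_rows.append(_signal_row(ts.name, "(all)", est))
            for spec in config.unmasking:
                unmasked = run_unmasking(reports, assignments, spec, ts.name,
                                         "combination", comparator,
                                         ic_method=config.ic_method)
                signal_rows.append(_signal_row(ts.name, f"(all, {spec.name})",
                                               unmasked))
        signals = pd.DataFrame(signal_rows)
        signals.to_csv(out / "signals.csv", index=False)

        stage = "sex_subgroups"
        subgroup_frames = []
        for ts in term_sets:
            sub = sex_subgroup_analysis(reports, assignments, ts,
                                        "combination",
                                        comparator if comparator != "database"
                                        else "glp1ra_only",
                                        ic_method=config.ic_method)
            frame = sub.estimates.assign(term_set=ts.name)
            frame["ratio_m_f"] = frame["pt"].map(
                lambda p: sub.ratios.get(p)).astype(float)
            subgroup_frames.append(frame)
        subgroups = pd.concat(subgroup_frames, ignore_index=True)
        subgroups.to_csv(out / "sex_subgroups.csv", index=False)

        stage = "tto"
        by_id = {r.report_id: r for r in reports}
        tto_rows, hist_rows = [], []
        for ts in term_sets:
            for exposure in ("combination", "glp1ra_only", "metformin_only"):
                samples = []
                for rid, a in assignments.items():
                    if a.exposure == exposure and a.event_flags.get(ts.name):
                        extracted = extract_tto(by_id[rid],
                                                _TARGET_CLASSES[exposure],
                                                exposure, ts.name)
                        if isinstance(extracted, TTOSample):
                            samples.append(extracted)
                if not samples:
                    continue
                med, q25, q75 = median_iqr(samples)
                row = {"term_set": ts.name, "exposure": exposure,
                       "n": len(samples), "median": med, "q25": q25, "q75": q75,
                       "alpha": None, "alpha_ci_low": None, "alpha_ci_high": None,
                       "beta": None, "beta_ci_low": None, "beta_ci_high": None,
                       "failure_type": None}
                try:
                    fit = fit_weibull(samples)
                    row.update(alpha=fit.scale_alpha,
                               alpha_ci_low=fit.scale_ci[0],
                               alpha_ci_high=fit.scale_ci[1],
                               beta=fit.shape_beta,
                               beta_ci_low=fit.shape_ci[0],
                               beta_ci_high=fit.shape_ci[1],
                               failure_type=fit.failure_type)
                except DegenerateSampleError:
                    pass
                tto_rows.append(row)
                hist = onset_histogram(samples)
                for label, count, pct in zip(hist.labels, hist.counts,
                                             hist.percentages):
                    hist_rows.append({"term_set": ts.name, "exposure": exposure,
                                      "bin": label, "count": count,
                                      "percentage": pct})
        tto = pd.DataFrame(tto_rows)
        tto.to_csv(out / "tto_weibull.csv", index=False)
        histogram = pd.DataFrame(hist_rows)
        histogram.to_csv(out / "onset_histogram.csv", index=False)

        stage = "reporting_years"
        years = pd.Series([r.receipt_date[:4] for r in reports], name="year")
        reporting_years = (years.value_counts().sort_index()
                           .rename("reports").reset_index())
        reporting_years.to_csv(out / "reporting_years.csv", index=False)

    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    results.update(
        reports=reports, assignments=assignments, descriptives=descriptives,
        signals=signals, subgroups=subgroups, tto=tto, histogram=histogram,
        reporting_years=reporting_years, cohort_sizes=cohort_sizes,
    )
    manifest = {
        "package": "pvfaers", "version": __version__,
        "config_hash": config.config_hash(), "seed": config.seed,
        "n_reports": len(reports), "cohort_sizes": cohort_sizes,
        "quarters": [b.quarter for b in bundles],
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def export_results(results: dict, directory: str | Path,
                   fmt: str = "csv") -> list[Path]:
    """Re-export the tabular results in ``csv`` or ``json`` with a stable
    column order; returns the written paths."""
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    tables = {k: v for k, v in results.items() if isinstance(v, pd.DataFrame)}
    for name, frame in sorted(tables.items()):
        path = directory / f"{name}.{fmt}"
        if fmt == "csv":
            frame.to_csv(path, index=False)
        else:
            path.write_text(frame.to_json(orient="table", index=False))
        paths.append(path)
    return paths
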