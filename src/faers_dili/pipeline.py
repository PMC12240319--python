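"""End-to-end orchestration: ingest -> dedup -> mapping -> cohort -> signals
-> descriptives -> report files.

``run_pipeline`` drives the fixed stage order from a :class:`RunConfig`
(YAML or JSON on disk), logs an attrition table (case counts in and out of
every stage) and writes the result CSVs plus run metadata.
``validate_printed`` recomputes the published reference statistics from
the packaged fixture of printed values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import descriptives, disprop
from .cohort import assemble_cohort, load_smq_terms
from .dedup import dedupe_cases
from .drug_map import STATINS, load_drug_dictionary
from .faers_io import read_database, write_faers_tables, write_results
from .synth import SyntheticConfig, generate

logger = logging.getLogger("faers_dili")


class RunConfig(BaseModel):
    """Fully describes one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    input_dir: Optional[Path] = None
    synthetic: Optional[SyntheticConfig] = None
    smq_path: Optional[Path] = None
    dictionary_path: Optional[Path] = None
    target_drugs: List[str] = Field(default_factory=lambda: list(STATINS))
    ic_ci_method: str = "noren"
    stratified: bool = True
    onset_method: str = "anova"
    output_dir: Path = Path("faers_dili_out")
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir or synthetic required")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        for path in (self.smq_path, self.dictionary_path):
            if path is not None and not Path(path).is_file():
                raise ValueError(f"configured path does not exist: {path}")
        if self.ic_ci_method not in disprop.IC_CI_METHODS:
            raise ValueError(f"unknown ic_ci_method {self.ic_ci_method!r}")
        unknown = set(self.target_drugs) - set(STATINS)
        if unknown:
            raise ValueError(f"target drugs outside the dictionary: {sorted(unknown)}")
        return self

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.model_validate(data)


class PipelineResult:
    def __init__(self) -> None:
        self.tables: Dict[str, pd.DataFrame] = {}
        self.attrition: List[dict] = []
        self.metadata: dict = {}
        self.manifest: dict = {}
        self.signals: List[disprop.SignalResult] = []

    def signal_for(self, drug: str) -> Optional[disprop.SignalResult]:
        for r in self.signals:
            if r.drug == drug and r.stratum is None:
                return r
        return None


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage in order and write the report bundle.

    Stage order: ingest (or synthesis) -> dedup -> PS statin mapping ->
    DILI classification and temporal exclusion -> contingency/signals
    (overall and age strata) -> descriptives and onset -> CSV reports.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    result = PipelineResult()
    out_dir = Path(config.output_dir)

    # --- ingest ----------------------------------------------------------
    if config.synthetic is not None:
        logger.info("generating synthetic database (n_cases=%d, seed=%d)",
                    config.synthetic.n_cases, config.synthetic.seed)
        raw_tables, truth = generate(config.synthetic)
        synth_dir = out_dir / "synthetic_input"
        write_faers_tables(raw_tables, synth_dir)
        tables, reports = read_database(synth_dir)
    else:
        tables, reports = read_database(config.input_dir)
        truth = None
    result.attrition.append({"stage": "ingest",
                             "n_in": sum(r.n_rows for r in reports.values()),
                             "n_out": sum(r.n_accepted for r in reports.values()),
                             "n_removed": sum(r.n_rejected for r in reports.values())})

    # --- dedup -----------------------------------------------------------
    linked = {k: tables[k] for k in ("DRUG", "REAC", "OUTC", "THER")}
    demo, linked, dedup_report = dedupe_cases(tables["DEMO"], linked)
    result.attrition.append({"stage": "dedup", "n_in": dedup_report.n_input,
                             "n_out": dedup_report.n_cases,
                             "n_removed": dedup_report.n_removed})
    logger.info("dedup: %d report versions -> %d cases", dedup_report.n_input,
                dedup_report.n_cases)

    # --- cohort (mapping + DILI classification + temporal exclusion) -----
    dictionary = load_drug_dictionary(config.dictionary_path)
    smq = load_smq_terms(config.smq_path)
    cohort = assemble_cohort(demo, linked["DRUG"], linked["REAC"],
                             linked["OUTC"], linked["THER"], dictionary, smq)
    excl = cohort.exclusion
    result.attrition.append({"stage": "temporal_exclusion",
                             "n_in": excl["n_input_cases"],
                             "n_out": excl["n_retained"],
                             "n_removed": excl["n_excluded_temporal"]})
    logger.info("cohort: %d retained (%d statin PS: %d DILI / %d non-DILI; "
                "%d comparator), %d excluded by the temporal rule",
                excl["n_retained"], excl["n_statin_cases"],
                excl["n_dili_statin"], excl["n_non_dili_statin"],
                excl["n_background_cases"], excl["n_excluded_temporal"])
    if excl["n_background_cases"] == 0:
        logger.warning("no comparator cases beyond the statin extract: RORs "
                       "are relative to the loaded statin universe, not the "
                       "full reporting database")

    # --- signals ---------------------------------------------------------
    signals = disprop.compute_signals(cohort.universe, config.target_drugs,
                                      ic_ci_method=config.ic_ci_method)
    if config.stratified:
        for drug in config.target_drugs:
            signals.extend(disprop.stratified_signals(
                cohort.universe, drug, ic_ci_method=config.ic_ci_method))
    result.signals = signals
    result.tables["signals"] = disprop.signals_frame(signals)

    # --- descriptives ----------------------------------------------------
    demo_tables = descriptives.demographics_table(cohort.dili, cohort.non_dili)
    result.tables["demographics"] = pd.concat(
        [t.tidy() for name, t in demo_tables.items() if name != "outcomes"],
        ignore_index=True)
    result.tables["outcomes"] = demo_tables["outcomes"].tidy()
    samples, n_onset_excluded = descriptives.onset_samples(cohort.dili)
    result.tables["onset"] = descriptives.onset_summary(samples)
    onset_cmp = descriptives.compare_onset(samples, method=config.onset_method)
    result.tables["onset_pairwise"] = onset_cmp.pairwise
    lo = min((int(y) for y in cohort.statin_cases["receipt_year"] if y > 0),
             default=2004)
    hi = max((int(y) for y in cohort.statin_cases["receipt_year"] if y > 0),
             default=2023)
    result.tables["annual_counts"] = descriptives.annual_counts(
        cohort.statin_cases, (lo, hi))
    trend = descriptives.dose_trend(cohort.dili)
    result.tables["dose_trend"] = pd.DataFrame({
        "dose_mg_per_day": list(trend.counts.index),
        "n_dili_cases": list(trend.counts.to_numpy()),
    })

    # --- reports ---------------------------------------------------------
    result.metadata = {
        "config_hash": _config_hash(config),
        "config": config.model_dump(mode="json"),
        "seed": config.seed,
        "attrition": result.attrition,
        "dedup": dedup_report.as_dict(),
        "exclusion": excl,
        "onset": {"n_excluded": n_onset_excluded,
                  "overall_method": onset_cmp.method,
                  "overall_p": onset_cmp.p_value},
        "dose_trend": {"trend_z": trend.trend_z, "trend_p": trend.trend_p,
                       "n_excluded": trend.n_excluded},
        "ingest": {k: r.as_dict() for k, r in reports.items()},
    }
    result.manifest = write_results(result.tables, out_dir, result.metadata)
    if truth is not None:
        truth_path = out_dir / "synthetic_truth.json"
        truth_path.write_text(json.dumps({
            "cells": {k: list(v) for k, v in truth.cells.items()},
            "n_cases": truth.n_cases, "n_duplicates": truth.n_duplicates,
            "planted_onset_median": truth.planted_onset_median,
        }, indent=2, sort_keys=True) + "\n")
    return result


# ---------------------------------------------------------------------------
# Validation against the published reference values
# ---------------------------------------------------------------------------

def load_printed_values() -> dict:
    """The packaged fixture of published reference statistics."""
    text = resources.files("faers_dili.data").joinpath(
        "printed_values.json").read_text()
    return json.loads(text)


def validate_printed(tolerance_ror: float = 0.01,
                     tolerance_ic: float = 0.02) -> dict:
    """Recompute the published statistics and report deviations.

    Three families of checks:

    * cross-prediction — the unprinted comparator odds are recovered by
      least squares from the four highest-count drugs' printed rows, then
      the held-out drugs' ROR/IC values are predicted from their printed
      case counts alone;
    * decision rule — the dual signal criteria applied to the printed
      point estimates and interval bounds must reproduce the published
      signal-positive set;
    * proportions — published percentages recomputed from their printed
      numerator/denominator pairs.
    """
    printed = load_printed_values()
    table = printed["signal_table"]
    checks: List[dict] = []

    def add(name: str, value: float, expected: float, tol: float) -> None:
        ok = bool(abs(value - expected) <= tol)
        checks.append({"check": name, "value": value, "expected": expected,
                       "tolerance": tol, "pass": ok})

    fit_drugs = ["atorvastatin", "rosuvastatin", "simvastatin", "pravastatin"]
    rows = {d: (table[d]["dili_cases"], table[d]["all_ae_cases"], table[d]["ror"])
            for d in fit_drugs}
    background = disprop.recover_background(rows)

    for drug, ic_key in [("fluvastatin", 2.65), ("cerivastatin", 3.46)]:
        a, b = table[drug]["dili_cases"], table[drug]["all_ae_cases"]
        ror = disprop.ror_from_background(a, b, background)
        add(f"{drug}_ror", ror, table[drug]["ror"],
            tolerance_ror * table[drug]["ror"])
        add(f"{drug}_ic", disprop.ic_from_background(a, b, background),
            table[drug]["ic"], tolerance_ic)
    for drug, bound in [("fluvastatin", "ror_l"), ("fluvastatin", "ror_u"),
                        ("pitavastatin", "ror_u")]:
        a, b = table[drug]["dili_cases"], table[drug]["all_ae_cases"]
        t = disprop.background_table(a, b, background)
        _, lo_v, hi_v = disprop.ror_estimate(t)
        value = lo_v if bound == "ror_l" else hi_v
        add(f"{drug}_{bound}", value, table[drug][bound],
            tolerance_ror * table[drug][bound])

    positive = set()
    for drug, row in table.items():
        t = disprop.background_table(row["dili_cases"], row["all_ae_cases"],
                                     background)
        r = disprop.classify_signal(
            drug, t, (row["ror"], row["ror_l"], row["ror_u"]),
            (row["ic"], row["ic_l"], row["ic_u"]))
        if r.signal:
            positive.add(drug)
    expected_positive = set(printed["published_signal_positive"])
    checks.append({"check": "signal_set", "value": sorted(positive),
                   "expected": sorted(expected_positive),
                   "pass": positive == expected_positive})

    for item in printed["proportions"]:
        value = descriptives.proportion(item["numerator"], item["denominator"])
        add(item["label"].replace(" ", "_"), value, item["percent"], 0.005)

    return {"background_odds": background.q,
            "background_proportion": background.p,
            "n_failed": sum(0 if c["pass"] else 1 for c in checks),
            "checks": checks}
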