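"""Synthetic FAERS-like databases with planted statistical structure.

The generator emits the five quarterly tables (DEMO/DRUG/REAC/OUTC/THER)
for a configurable number of cases together with a *truth ledger*: the
exact per-case assignments and the realized 2x2 cells implied by them.
Every pipeline stage can therefore be checked against planted truth
without downloading anything.

Planted structure
-----------------
Each case draws one primary-suspect drug (a statin or a "background"
drug), then a DILI flag from that drug's planted reporting odds ratio
applied to the background DILI odds; DILI cases receive a hepatic SMQ
Preferred Term, others draw from a disjoint non-hepatic pool.
Demographics come from categorical mixes, time-to-onset from per-drug
log-normal latencies (therapy start = event date minus latency, so the
temporal exclusion never bites by construction), and daily doses from
per-drug weight tables.  Duplicate report versions and brand/salt name
variants are injected at configurable rates; duplicates are built so the
intended survivor of the FDA dedup rule is known, with a "hostile" mode
whose duplicates either tie on FDA_DT (the PRIMARYID tie-break must
decide) or carry a higher PRIMARYID with an earlier FDA_DT (the date rule
must override the id).

What this emulates and what it does not: marginal distributions and the
drug-DILI association structure of a spontaneous-report database, not
reporting biases (Weber effect, stimulated reporting), real MedDRA coding
noise, or free-text drug-name chaos beyond dictionary-listed variants.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import load_smq_terms, normalize_pt
from .drug_map import STATINS, load_drug_dictionary

#: Non-hepatic Preferred Terms drawn by non-DILI cases; disjoint from the
#: packaged SMQ fixture so classification is unambiguous in tests.
BACKGROUND_PTS = (
    "Headache", "Nausea", "Dizziness", "Myalgia", "Rhabdomyolysis",
    "Arthralgia", "Fatigue", "Rash", "Diarrhoea", "Vomiting",
    "Muscle spasms", "Insomnia", "Pruritus", "Cough", "Dyspnoea",
    "Constipation", "Abdominal pain upper", "Back pain", "Pyrexia",
    "Blood creatine phosphokinase increased", "Memory impairment",
    "Oedema peripheral", "Hypertension", "Fall",
)

#: Primary-suspect names for the comparator bucket; none map to a statin.
BACKGROUND_DRUGS = (
    "METFORMIN", "LISINOPRIL", "AMLODIPINE", "OMEPRAZOLE", "ASPIRIN",
    "LEVOTHYROXINE", "ALBUTEROL", "GABAPENTIN", "HYDROCHLOROTHIAZIDE",
    "SERTRALINE", "IBUPROFEN", "WARFARIN", "INSULIN GLARGINE",
    "PREDNISONE", "CLOPIDOGREL", "FUROSEMIDE",
)

_REGION_COUNTRY = {
    "north_america": "US", "europe": "FR", "asia": "JP", "oceania": "AU",
    "south_america": "BR", "africa": "ZA", "unspecified": "",
}

_DEFAULT_SHARES = {
    "atorvastatin": 0.2475, "rosuvastatin": 0.1259, "simvastatin": 0.0933,
    "pravastatin": 0.0190, "fluvastatin": 0.0047, "lovastatin": 0.0044,
    "pitavastatin": 0.0049, "cerivastatin": 0.0002, "background": 0.5001,
}

_DEFAULT_ROR = {
    "atorvastatin": 3.09, "rosuvastatin": 2.27, "simvastatin": 2.96,
    "pravastatin": 2.07, "fluvastatin": 6.90, "lovastatin": 2.77,
    "pitavastatin": 1.88, "cerivastatin": 13.33,
}

#: Per-drug log-normal latency parameters (mu in log-days); medians follow
#: the published per-statin onset medians, sigma wide enough for IQRs
#: spanning roughly a decade.
_DEFAULT_ONSET = {
    "atorvastatin": (math.log(24.5), 1.6), "rosuvastatin": (math.log(21.0), 1.6),
    "simvastatin": (math.log(35.0), 1.6), "pravastatin": (math.log(41.0), 1.6),
    "fluvastatin": (math.log(20.0), 1.2), "lovastatin": (math.log(89.0), 1.2),
    "pitavastatin": (math.log(48.0), 1.2), "cerivastatin": (math.log(30.0), 1.2),
    "background": (math.log(30.0), 1.5),
}

_DEFAULT_DOSES = {
    "atorvastatin": {10.0: 471, 20.0: 530, 40.0: 590, 80.0: 655},
}
_GENERIC_DOSES = {10.0: 1, 20.0: 1, 40.0: 1}


class SyntheticConfig(BaseModel):
    """Generator settings; defaults approximate the published statin case mix."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_cases: int = 10_000
    drug_shares: Dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_SHARES))
    background_dili_prob: float = 0.01695
    drug_ror: Dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_ROR))
    stratum_ror: Optional[Dict[str, Dict[str, float]]] = None
    age_mix: Tuple[float, float, float] = (0.3217, 0.3630, 0.3153)  # <65, >=65, unknown
    sex_mix: Dict[str, float] = Field(default_factory=lambda: {
        "female": 0.4761, "male": 0.4221, "unknown": 0.1018})
    reporter_mix: Dict[str, float] = Field(default_factory=lambda: {
        "health_professional": 0.4696, "non_health_professional": 0.4290,
        "unknown": 0.1014})
    region_mix: Dict[str, float] = Field(default_factory=lambda: {
        "north_america": 0.5590, "europe": 0.2782, "asia": 0.0452,
        "oceania": 0.0118, "south_america": 0.0361, "africa": 0.0039,
        "unspecified": 0.0658})
    outcome_probs: Dict[str, Dict[str, float]] = Field(default_factory=lambda: {
        "dili": {"DE": 0.0873, "LT": 0.0755, "HO": 0.3995, "DS": 0.0185,
                 "CA": 0.0003, "RI": 0.0058, "OT": 0.3666, "none": 0.0465},
        "non_dili": {"DE": 0.0453, "LT": 0.0349, "HO": 0.1782, "DS": 0.0537,
                     "CA": 0.0013, "RI": 0.0081, "OT": 0.4033, "none": 0.2752},
    })
    onset_lognormal: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: dict(_DEFAULT_ONSET))
    dose_weights: Dict[str, Dict[float, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_DOSES.items()})
    duplicate_rate: float = 0.10
    hostile_ties: bool = False
    brand_variant_rate: float = 0.30
    missing_date_rate: float = 0.15
    year_range: Tuple[int, int] = (2004, 2023)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        for name, dist in [("drug_shares", self.drug_shares),
                           ("sex_mix", self.sex_mix),
                           ("reporter_mix", self.reporter_mix),
                           ("region_mix", self.region_mix)]:
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        if abs(sum(self.age_mix) - 1.0) > 1e-6:
            raise ValueError("age_mix must sum to 1")
        if not 0.0 < self.background_dili_prob < 1.0:
            raise ValueError("background_dili_prob must lie in (0, 1)")
        for drug in self.drug_shares:
            if drug != "background" and drug not in STATINS:
                raise ValueError(f"unknown drug in drug_shares: {drug!r}")
        q0 = self.background_dili_prob / (1.0 - self.background_dili_prob)
        for drug, ror in self.drug_ror.items():
            if ror <= 0:
                raise ValueError(f"planted ROR for {drug} must be positive")
            if not 0.0 < ror * q0 / (1.0 + ror * q0) < 1.0:
                raise ValueError(f"planted ROR for {drug} implies an "
                                 "impossible DILI probability")
        for status, probs in self.outcome_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"outcome_probs[{status}] must sum to 1")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1]")
        if not 0.0 <= self.missing_date_rate <= 1.0:
            raise ValueError("missing_date_rate must lie in [0, 1]")
        return self


@dataclasses.dataclass
class SyntheticTruth:
    """Planted parameters paired with the realized per-case assignments."""

    config: SyntheticConfig
    assignments: pd.DataFrame  # one row per case (survivor version)
    cells: Dict[str, Tuple[int, int, int, int]]
    duplicate_map: Dict[str, List[str]]
    planted_onset_median: Dict[str, float]

    @property
    def n_cases(self) -> int:
        return len(self.assignments)

    @property
    def n_duplicates(self) -> int:
        return sum(len(v) for v in self.duplicate_map.values())


def _pick(rng: np.random.Generator, table: Dict[str, float], n: int) -> np.ndarray:
    keys = list(table)
    probs = np.asarray([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=n, p=probs)]


def _degrade_dates(rng: np.random.Generator, digits: np.ndarray,
                   rate: float) -> np.ndarray:
    """Randomly degrade day-precision date strings to month/year/missing."""
    if rate <= 0:
        return digits
    u = rng.random(len(digits))
    out = digits.copy()
    month = u < 0.5 * rate
    year = (u >= 0.5 * rate) & (u < 0.75 * rate)
    missing = (u >= 0.75 * rate) & (u < rate)
    out[month] = [d[:6] for d in out[month]]
    out[year] = [d[:4] for d in out[year]]
    out[missing] = ""
    return out


def generate(config: SyntheticConfig):
    """Generate the five raw tables and the truth ledger.

    Returns ``(tables, truth)`` where ``tables`` maps DEMO/DRUG/REAC/OUTC/
    THER to DataFrames in the raw "$"-file column layout (all strings), and
    ``truth`` is a :class:`SyntheticTruth`.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    dictionary = load_drug_dictionary()
    smq_terms = sorted(load_smq_terms().terms)  # normalized strings
    overlap = set(normalize_pt(p) for p in BACKGROUND_PTS) & set(smq_terms)
    if overlap:  # guards the fixture contract, not user input
        raise RuntimeError(f"background PT pool overlaps SMQ fixture: {overlap}")

    # --- per-case assignments -------------------------------------------
    drug = _pick(rng, config.drug_shares, n)
    age_group = np.asarray(["<65", ">=65", "unknown"], dtype=object)[
        rng.choice(3, size=n, p=np.asarray(config.age_mix))]
    age_years = np.where(age_group == "<65",
                         rng.integers(18, 65, size=n),
                         rng.integers(65, 91, size=n)).astype(float)
    age_years[age_group == "unknown"] = np.nan
    sex = _pick(rng, config.sex_mix, n)
    reporter = _pick(rng, config.reporter_mix, n)
    region = _pick(rng, config.region_mix, n)

    q0 = config.background_dili_prob / (1.0 - config.background_dili_prob)
    ror = np.asarray([config.drug_ror.get(d, 1.0) for d in drug])
    if config.stratum_ror:
        for i, (d, g) in enumerate(zip(drug, age_group)):
            override = config.stratum_ror.get(d, {}).get(g)
            if override is not None:
                ror[i] = override
    odds = ror * q0
    p_dili = odds / (1.0 + odds)
    is_dili = rng.random(n) < p_dili

    lo, hi = config.year_range
    first = np.datetime64(f"{lo}-01-01")
    last = np.datetime64(f"{hi}-12-31")
    span = int((last - first) / np.timedelta64(1, "D")) + 1
    event = first + rng.integers(0, span, size=n).astype("timedelta64[D]")
    mu = np.asarray([config.onset_lognormal.get(d, (math.log(30.0), 1.5))[0]
                     for d in drug])
    sigma = np.asarray([config.onset_lognormal.get(d, (math.log(30.0), 1.5))[1]
                        for d in drug])
    onset = np.round(rng.lognormal(mu, sigma)).astype(int)
    start = event - onset.astype("timedelta64[D]")
    fda = np.minimum(event + rng.integers(2, 120, size=n).astype("timedelta64[D]"),
                     last)

    def _digits(arr: np.ndarray) -> np.ndarray:
        return np.asarray(pd.Series(arr).dt.strftime("%Y%m%d"), dtype=object)

    event_digits = _degrade_dates(rng, _digits(event), config.missing_date_rate)
    start_digits = _degrade_dates(rng, _digits(start), config.missing_date_rate)
    fda_digits = _digits(fda)
    receipt_year = np.asarray([int(d[:4]) for d in fda_digits])

    # doses (per drug; background cases carry none)
    dose = np.full(n, np.nan)
    for d in set(drug):
        if d == "background":
            continue
        weights = config.dose_weights.get(d, _GENERIC_DOSES)
        idx = np.flatnonzero(drug == d)
        levels = sorted(weights)
        p = np.asarray([weights[x] for x in levels], dtype=float)
        dose[idx] = np.asarray(levels)[rng.choice(len(levels), size=len(idx),
                                                  p=p / p.sum())]

    caseid = np.asarray([str(100000 + i) for i in range(n)], dtype=object)
    pid = np.asarray([str(10 * i + 5) for i in range(n)], dtype=object)

    # --- DEMO (survivor versions) ---------------------------------------
    sex_code = {"female": "F", "male": "M", "unknown": ""}
    rep_code = {"health_professional": "MD", "non_health_professional": "CN",
                "unknown": ""}
    age_str = np.asarray(["" if a != a else str(int(a)) for a in age_years],
                         dtype=object)
    age_cod = np.where(age_str == "", "", "YR").astype(object)
    # a slice of known ages is reported in months to exercise unit conversion
    months_mask = (age_str != "") & (rng.random(n) < 0.1)
    age_str[months_mask] = [str(int(float(a) * 12)) for a in age_str[months_mask]]
    age_cod[months_mask] = "MON"

    demo_rows = {
        "primaryid": pid, "caseid": caseid, "fda_dt": fda_digits,
        "event_dt": event_digits, "age": age_str, "age_cod": age_cod,
        "sex": np.asarray([sex_code[s] for s in sex], dtype=object),
        "occp_cod": np.asarray([rep_code[r] for r in reporter], dtype=object),
        "reporter_country": np.asarray([_REGION_COUNTRY[r] for r in region],
                                       dtype=object),
    }

    # --- DRUG / THER -----------------------------------------------------
    variant_cache = {g: [v for v in dictionary.variants_of(g) if v != g.upper()]
                     for g in STATINS}
    use_variant = rng.random(n) < config.brand_variant_rate
    names = np.empty(n, dtype=object)
    for i, d in enumerate(drug):
        if d == "background":
            names[i] = BACKGROUND_DRUGS[rng.integers(len(BACKGROUND_DRUGS))]
        elif use_variant[i] and variant_cache[d]:
            names[i] = variant_cache[d][rng.integers(len(variant_cache[d]))]
        else:
            names[i] = d.upper()

    drug_cols = {
        "primaryid": list(pid), "drug_seq": ["1"] * n, "role_cod": ["PS"] * n,
        "drugname": list(names),
        "dose_amt": ["" if v != v else f"{v:g}" for v in dose],
        "dose_unit": ["" if v != v else "MG" for v in dose],
        "dose_freq": ["" if v != v else "QD" for v in dose],
    }
    ther_cols = {"primaryid": list(pid), "dsg_drug_seq": ["1"] * n,
                 "start_dt": list(start_digits)}

    # concomitant rows (role C) exercise the PS restriction
    conc_mask = rng.random(n) < 0.2
    for i in np.flatnonzero(conc_mask):
        drug_cols["primaryid"].append(pid[i])
        drug_cols["drug_seq"].append("2")
        drug_cols["role_cod"].append("C")
        drug_cols["drugname"].append(
            BACKGROUND_DRUGS[rng.integers(len(BACKGROUND_DRUGS))])
        drug_cols["dose_amt"].append("")
        drug_cols["dose_unit"].append("")
        drug_cols["dose_freq"].append("")
    # occasional secondary-suspect statin on background cases: must NOT
    # count as exposure
    ss_mask = (drug == "background") & (rng.random(n) < 0.05)
    for i in np.flatnonzero(ss_mask):
        drug_cols["primaryid"].append(pid[i])
        drug_cols["drug_seq"].append("3")
        drug_cols["role_cod"].append("SS")
        drug_cols["drugname"].append(STATINS[rng.integers(len(STATINS))].upper())
        drug_cols["dose_amt"].append("")
        drug_cols["dose_unit"].append("")
        drug_cols["dose_freq"].append("")

    # --- REAC ------------------------------------------------------------
    reac_pid: List[str] = []
    reac_pt: List[str] = []
    second_smq = rng.random(n) < 0.15
    extra_bg = rng.random(n) < 0.3
    smq_idx = rng.integers(0, len(smq_terms), size=(n, 2))
    bg_idx = rng.integers(0, len(BACKGROUND_PTS), size=(n, 2))
    for i in range(n):
        if is_dili[i]:
            reac_pid.append(pid[i])
            reac_pt.append(smq_terms[smq_idx[i, 0]].title())
            if second_smq[i] and smq_idx[i, 1] != smq_idx[i, 0]:
                reac_pid.append(pid[i])
                reac_pt.append(smq_terms[smq_idx[i, 1]].title())
            if extra_bg[i]:
                reac_pid.append(pid[i])
                reac_pt.append(BACKGROUND_PTS[bg_idx[i, 0]])
        else:
            reac_pid.append(pid[i])
            reac_pt.append(BACKGROUND_PTS[bg_idx[i, 0]])
            if extra_bg[i] and bg_idx[i, 1] != bg_idx[i, 0]:
                reac_pid.append(pid[i])
                reac_pt.append(BACKGROUND_PTS[bg_idx[i, 1]])

    # --- OUTC ------------------------------------------------------------
    outc_pid: List[str] = []
    outc_cod: List[str] = []
    dili_outcome = _pick(rng, config.outcome_probs["dili"], n)
    non_outcome = _pick(rng, config.outcome_probs["non_dili"], n)
    outcome = np.where(is_dili, dili_outcome, non_outcome)
    for i in range(n):
        if outcome[i] != "none":
            outc_pid.append(pid[i])
            outc_cod.append(outcome[i])

    # --- duplicate report versions --------------------------------------
    duplicate_map: Dict[str, List[str]] = {}
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_rows = {k: [] for k in demo_rows}
    for j, i in enumerate(np.flatnonzero(dup_mask)):
        hostile_tie = config.hostile_ties and j % 2 == 0
        if hostile_tie:
            # same FDA_DT, lower PRIMARYID: the id tie-break must decide
            dup_pid = str(10 * i + 1 + rng.integers(4))
            dup_fda = fda_digits[i]
        elif config.hostile_ties:
            # higher PRIMARYID but earlier FDA_DT: the date must override
            dup_pid = str(10 * i + 6 + rng.integers(4))
            dup_fda = (pd.Timestamp(fda[i]) - pd.Timedelta(
                days=int(rng.integers(10, 200)))).strftime("%Y%m%d")
        else:
            dup_pid = str(10 * i + 1 + rng.integers(4))
            dup_fda = (pd.Timestamp(fda[i]) - pd.Timedelta(
                days=int(rng.integers(10, 200)))).strftime("%Y%m%d")
        duplicate_map.setdefault(caseid[i], []).append(dup_pid)
        dup_rows["primaryid"].append(dup_pid)
        dup_rows["caseid"].append(caseid[i])
        dup_rows["fda_dt"].append(dup_fda)
        dup_rows["event_dt"].append("")
        dup_rows["age"].append("")
        dup_rows["age_cod"].append("")
        dup_rows["sex"].append("")
        dup_rows["occp_cod"].append("")
        dup_rows["reporter_country"].append("")
        # earlier versions carry a non-hepatic PT and the same drug, so
        # keeping the wrong version flips the case's DILI status
        drug_cols["primaryid"].append(dup_pid)
        drug_cols["drug_seq"].append("1")
        drug_cols["role_cod"].append("PS")
        drug_cols["drugname"].append(names[i])
        drug_cols["dose_amt"].append("")
        drug_cols["dose_unit"].append("")
        drug_cols["dose_freq"].append("")
        reac_pid.append(dup_pid)
        reac_pt.append(BACKGROUND_PTS[rng.integers(len(BACKGROUND_PTS))])

    demo = pd.DataFrame({k: list(v) + dup_rows[k] for k, v in demo_rows.items()})
    tables = {
        "DEMO": demo,
        "DRUG": pd.DataFrame(drug_cols),
        "REAC": pd.DataFrame({"primaryid": reac_pid, "pt": reac_pt}),
        "OUTC": pd.DataFrame({"primaryid": outc_pid, "outc_cod": outc_cod}),
        "THER": pd.DataFrame(ther_cols),
    }

    assignments = pd.DataFrame({
        "caseid": caseid, "primaryid": pid,
        "drug": ["" if d == "background" else d for d in drug],
        "is_dili": is_dili, "age_group": age_group, "age_years": age_years,
        "sex": sex, "reporter": reporter, "region": region,
        "onset_days": onset, "dose_mg": dose, "receipt_year": receipt_year,
        "worst_outcome": ["unknown" if o == "none" else o for o in outcome],
    })
    total_dili = int(is_dili.sum())
    cells = {}
    for g in STATINS:
        a = int(((drug == g) & is_dili).sum())
        b = int(((drug == g) & ~is_dili).sum())
        cells[g] = (a, b, total_dili - a, (n - total_dili) - b)
    truth = SyntheticTruth(
        config=config, assignments=assignments, cells=cells,
        duplicate_map=duplicate_map,
        planted_onset_median={
            d: math.exp(config.onset_lognormal.get(d, (math.log(30.0), 1.5))[0])
            for d in set(drug)},
    )
    return tables, truth


def paper_scale_config(n_cases: int = 50_000, seed: int = 0) -> SyntheticConfig:
    """A configuration mirroring the published statin case mix at desk scale.

    Statins take half of the database (their relative shares follow the
    published per-drug totals), the other half is the comparator bucket;
    planted RORs are the published per-drug values, so the expected
    atorvastatin share of DILI cases is ~53% and fluvastatin carries the
    strongest planted signal among the evaluable drugs.
    """
    totals = {  # per-drug total case counts from the published table
        "atorvastatin": 82722, "rosuvastatin": 42091, "simvastatin": 31184,
        "pravastatin": 6362, "fluvastatin": 1584, "lovastatin": 1487,
        "pitavastatin": 1650, "cerivastatin": 32,
    }
    grand = sum(totals.values())
    shares = {d: 0.5 * v / grand for d, v in totals.items()}
    shares["background"] = 1.0 - sum(shares.values())
    return SyntheticConfig(seed=seed, n_cases=n_cases, drug_shares=shares)


def simulate_ror_replicates(n_replicates: int, planted_ror: float,
                            n_target: int, n_comparator: int,
                            p0: float, seed: int = 0) -> pd.DataFrame:
    """Cell-level replicates for interval-coverage studies.

    Each replicate draws the DILI counts of a target drug (odds =
    planted_ror * background odds) and of the comparator directly, then
    computes the ROR and its Woolf 95% CI.  Returns one row per replicate
    with the cells, estimates and a ``covered`` flag for the planted value.
    """
    from .disprop import ContingencyTable, ror_estimate

    rng = np.random.default_rng(seed)
    q0 = p0 / (1.0 - p0)
    pt = planted_ror * q0 / (1.0 + planted_ror * q0)
    a = rng.binomial(n_target, pt, size=n_replicates)
    c = rng.binomial(n_comparator, p0, size=n_replicates)
    rows = []
    for ai, ci in zip(a, c):
        t = ContingencyTable(int(ai), n_target - int(ai), int(ci),
                             n_comparator - int(ci))
        ror, lo, hi = ror_estimate(t)
        covered = (lo == lo) and lo <= planted_ror <= hi
        rows.append({"a": t.a, "b": t.b, "c": t.c, "d": t.d, "ror": ror,
                     "ror_l": lo, "ror_u": hi, "covered": covered})
    return pd.DataFrame(rows)
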