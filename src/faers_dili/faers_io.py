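"""Reading and writing of FAERS-style quarterly ASCII tables.

The FDA Adverse Event Reporting System distributes each quarter as a set of
"$"-delimited text files: patient demographics (DEMO), reported drugs (DRUG),
adverse reactions coded as MedDRA Preferred Terms (REAC), patient outcomes
(OUTC) and therapy dates (THER).  This module parses those files into
validated :class:`pandas.DataFrame` tables with a canonical column set,
handles FAERS's 4/6/8-digit partial dates, converts reported ages to years
and rolls reporter countries up to continental regions.

Column binding is header-driven and case-insensitive because the FAERS
schema changed across quarters; unknown extra columns are ignored.  Row
level malformation is never fatal: bad rows are rejected, counted and
reported.  A missing *mandatory* column is a hard error.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger("faers_dili")

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER")

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: FDA outcome codes: death, life-threatening, hospitalization, disability,
#: congenital anomaly, required intervention, other serious.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

REGIONS = (
    "north_america",
    "europe",
    "asia",
    "oceania",
    "south_america",
    "africa",
    "unspecified",
)

#: Age unit codes and their conversion factors to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: Reported ages outside this range (in years) are treated as unknown; the
#: raw files contain unit typos that would otherwise yield impossible ages.
AGE_RANGE_YEARS = (0.0, 120.0)

#: FAERS occupation codes rolled up to the reporter categories used in
#: demographic tables.
_HEALTH_PROFESSIONAL_CODES = {"MD", "PH", "HP", "OT"}
_NON_HEALTH_PROFESSIONAL_CODES = {"CN", "LW"}


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=False)
class PartialDate:
    """A FAERS date at year, month or day precision.

    FAERS date fields are numeric strings of length 4 (``YYYY``), 6
    (``YYYYMM``) or 8 (``YYYYMMDD``).  ``month``/``day`` are ``None`` when
    the component is not reported.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day precision requires a month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # must be a real calendar date
            _dt.date(self.year, self.month, self.day)

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def digits(self) -> str:
        """The canonical 4/6/8-digit string for this date."""
        s = f"{self.year:04d}"
        if self.month is not None:
            s += f"{self.month:02d}"
        if self.day is not None:
            s += f"{self.day:02d}"
        return s

    def to_date(self) -> _dt.date:
        """Calendar date; only defined at day precision."""
        if self.precision != "day":
            raise ValueError("to_date() requires day precision")
        return _dt.date(self.year, self.month, self.day)

    @classmethod
    def from_digits(cls, digits: str) -> "PartialDate":
        return parse_partial_date(digits, strict=True)


def parse_partial_date(raw: object, *, strict: bool = False) -> Optional[PartialDate]:
    """Parse a FAERS date string; malformation yields ``None``, never raises.

    Accepts 4-digit (year), 6-digit (month) and 8-digit (day) forms.  An
    invalid calendar value (e.g. ``20230231``) is treated as missing.  With
    ``strict=True`` malformed input raises instead (used internally).
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if s.endswith(".0"):  # tolerate float round-trips of numeric columns
        s = s[:-2]
    if not s or not s.isdigit() or len(s) not in (4, 6, 8):
        if strict and s:
            raise ValueError(f"not a FAERS date: {raw!r}")
        return None
    try:
        year = int(s[:4])
        month = int(s[4:6]) if len(s) >= 6 else None
        day = int(s[6:8]) if len(s) == 8 else None
        return PartialDate(year, month, day)
    except ValueError:
        if strict:
            raise
        return None


def compare_partial(a: Optional[PartialDate], b: Optional[PartialDate]) -> Optional[int]:
    """Compare two partial dates at their coarsest common precision.

    Returns -1/0/+1, or ``None`` when either date is missing (incomparable).
    ``PartialDate(2023)`` and ``PartialDate(2023, 3, 15)`` compare equal:
    at year precision neither is later than the other.
    """
    if a is None or b is None:
        return None
    n = min(len(a.digits()), len(b.digits()))
    da, db = a.digits()[:n], b.digits()[:n]
    return (da > db) - (da < db)


# ---------------------------------------------------------------------------
# Typed records (row-level view of the validated tables)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: Optional[PartialDate]
    event_dt: Optional[PartialDate] = None
    age_value: Optional[float] = None
    age_unit: Optional[str] = None
    age_years: Optional[float] = None
    sex: str = "unknown"
    reporter: str = "unknown"
    country: Optional[str] = None
    region: str = "unspecified"


@dataclass(frozen=True)
class DrugEntry:
    primaryid: str
    drug_seq: int
    role: str
    raw_name: str
    dose_amount: Optional[float] = None
    dose_unit: Optional[str] = None
    dose_frequency: Optional[str] = None


@dataclass(frozen=True)
class ReacEntry:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class OutcEntry:
    primaryid: str
    outcome: str


@dataclass(frozen=True)
class TherEntry:
    primaryid: str
    dsg_drug_seq: int
    start_dt: Optional[PartialDate] = None


@dataclass
class IngestReport:
    """Bookkeeping for one table read: accepted + rejected = physical rows."""

    table_kind: str
    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    reject_reasons: Counter = field(default_factory=Counter)
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "table_kind": self.table_kind,
            "n_rows": self.n_rows,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "reject_reasons": dict(self.reject_reasons),
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# Field conversions
# ---------------------------------------------------------------------------

def age_in_years(age_value: Optional[float], age_unit: Optional[str]) -> Optional[float]:
    """Convert a reported (value, unit) age to years.

    Unknown units and converted values outside the plausibility window
    [0, 120] years yield ``None`` (unknown).
    """
    if age_value is None or age_value != age_value or age_value < 0:
        return None
    unit = (age_unit or "").strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        if unit:
            logger.debug("unrecognized age unit %r -> unknown", age_unit)
        return None
    years = float(age_value) * factor
    lo, hi = AGE_RANGE_YEARS
    if not lo <= years <= hi:
        logger.debug("age %s %s -> %.1f years outside [0,120] -> unknown",
                     age_value, age_unit, years)
        return None
    return years


_REGION_TABLE: Optional[dict] = None


def _region_table() -> dict:
    global _REGION_TABLE
    if _REGION_TABLE is None:
        with resources.files("faers_dili.data").joinpath("country_regions.csv").open() as fh:
            df = pd.read_csv(fh)
        _REGION_TABLE = dict(zip(df["country"], df["region"]))
    return _REGION_TABLE


def to_region(country: Optional[str]) -> str:
    """Map an ISO-3166 alpha-2 country code to a reporting region.

    Unknown or absent codes map to ``unspecified``.
    """
    code = (country or "").strip().upper()
    if not code:
        return "unspecified"
    return _region_table().get(code, "unspecified")


def _map_sex(raw: str) -> str:
    code = raw.strip().upper()
    if code == "F":
        return "female"
    if code == "M":
        return "male"
    return "unknown"


def _map_reporter(raw: str) -> str:
    code = raw.strip().upper()
    if code in _HEALTH_PROFESSIONAL_CODES:
        return "health_professional"
    if code in _NON_HEALTH_PROFESSIONAL_CODES:
        return "non_health_professional"
    return "unknown"


def _clean_date_digits(raw: str) -> str:
    """Canonical digit string for a date field, '' when missing/invalid."""
    pd_ = parse_partial_date(raw)
    return pd_.digits() if pd_ is not None else ""


# ---------------------------------------------------------------------------
# Table reading
# ---------------------------------------------------------------------------

# mandatory columns per table kind, with accepted header aliases
_SCHEMAS = {
    "DEMO": {
        "mandatory": {"primaryid": ["primaryid"], "caseid": ["caseid"],
                      "fda_dt": ["fda_dt"]},
        "optional": {"event_dt": ["event_dt"], "age": ["age", "age_value"],
                     "age_cod": ["age_cod", "age_unit"],
                     "sex": ["sex", "gndr_cod"], "occp_cod": ["occp_cod"],
                     "reporter_country": ["reporter_country", "country"]},
    },
    "DRUG": {
        "mandatory": {"primaryid": ["primaryid"],
                      "drug_seq": ["drug_seq", "dsg_drug_seq"],
                      "role_cod": ["role_cod", "role"],
                      "drugname": ["drugname", "drug_name", "raw_name"]},
        "optional": {"dose_amt": ["dose_amt", "dose_amount"],
                     "dose_unit": ["dose_unit"],
                     "dose_freq": ["dose_freq", "dose_frequency"]},
    },
    "REAC": {
        "mandatory": {"primaryid": ["primaryid"], "pt": ["pt"]},
        "optional": {},
    },
    "OUTC": {
        "mandatory": {"primaryid": ["primaryid"],
                      "outc_cod": ["outc_cod", "outc_code", "outcome"]},
        "optional": {},
    },
    "THER": {
        "mandatory": {"primaryid": ["primaryid"],
                      "dsg_drug_seq": ["dsg_drug_seq", "drug_seq"]},
        "optional": {"start_dt": ["start_dt"]},
    },
}


class MissingColumnError(ValueError):
    """A mandatory column is absent from the header."""


def _bind_columns(header: Sequence[str], kind: str) -> dict:
    """Map canonical field -> column index, honouring header aliases."""
    schema = _SCHEMAS[kind]
    lower = [h.strip().lower() for h in header]
    binding = {}
    for canon, aliases in {**schema["mandatory"], **schema["optional"]}.items():
        for alias in aliases:
            if alias in lower:
                binding[canon] = lower.index(alias)
                break
    for canon in schema["mandatory"]:
        if canon not in binding:
            raise MissingColumnError(
                f"{kind} table is missing mandatory column {canon!r}")
    return binding


def read_table(source: Union[str, Path, Iterable[str]], table_kind: str):
    """Read one "$"-delimited FAERS table.

    Parameters
    ----------
    source
        Path to the file, or an iterable of lines (header first).
    table_kind
        One of ``DEMO, DRUG, REAC, OUTC, THER``.

    Returns
    -------
    (pandas.DataFrame, IngestReport)
        The frame carries the canonical columns for the table kind; every
        row satisfies the type invariants.  Rejected rows are counted in the
        report with reasons.
    """
    kind = table_kind.upper()
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", errors="replace") as fh:
            lines = fh.read().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]
    if not lines:
        raise MissingColumnError(f"{kind} table has no header line")
    header = lines[0].split("$")
    binding = _bind_columns(header, kind)
    n_fields = len(header)
    report = IngestReport(table_kind=kind)

    rows = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        report.n_rows += 1
        parts = ln.split("$")
        if len(parts) != n_fields:
            report.n_rejected += 1
            report.reject_reasons["field_count_mismatch"] += 1
            continue
        rec = {canon: parts[idx].strip() for canon, idx in binding.items()}
        reason = _validate_row(rec, kind)
        if reason is not None:
            report.n_rejected += 1
            report.reject_reasons[reason] += 1
            continue
        rows.append(rec)
    report.n_accepted = len(rows)
    frame = _finalize_frame(rows, kind)
    logger.info("read %s: %d rows, %d accepted, %d rejected",
                kind, report.n_rows, report.n_accepted, report.n_rejected)
    return frame, report


def _validate_row(rec: dict, kind: str) -> Optional[str]:
    if not rec.get("primaryid", ""):
        return "empty_primaryid"
    if kind == "DEMO":
        if not rec.get("caseid", ""):
            return "empty_caseid"
    elif kind == "DRUG":
        if not rec["drug_seq"].isdigit() or int(rec["drug_seq"]) < 1:
            return "bad_drug_seq"
        if rec["role_cod"].strip().upper() not in ROLE_CODES:
            return "bad_role_code"
        if not rec["drugname"].strip():
            return "empty_drugname"
    elif kind == "REAC":
        if not " ".join(rec["pt"].split()):
            return "empty_pt"
    elif kind == "OUTC":
        if rec["outc_cod"].strip().upper() not in OUTCOME_CODES:
            return "bad_outcome_code"
    elif kind == "THER":
        if not rec["dsg_drug_seq"].isdigit() or int(rec["dsg_drug_seq"]) < 1:
            return "bad_drug_seq"
    return None


_CANONICAL_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "age_value",
             "age_unit", "age_years", "sex", "reporter", "country", "region"],
    "DRUG": ["primaryid", "drug_seq", "role", "raw_name", "dose_amount",
             "dose_unit", "dose_frequency"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outcome"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
}


def _finalize_frame(rows: list, kind: str) -> pd.DataFrame:
    cols = _CANONICAL_COLUMNS[kind]
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    raw = pd.DataFrame(rows)
    out = pd.DataFrame(index=raw.index)
    out["primaryid"] = raw["primaryid"]
    if kind == "DEMO":
        out["caseid"] = raw["caseid"]
        out["fda_dt"] = raw["fda_dt"].map(_clean_date_digits)
        out["event_dt"] = raw.get("event_dt", pd.Series("", index=raw.index)).map(_clean_date_digits)
        age_raw = raw.get("age", pd.Series("", index=raw.index))
        out["age_value"] = pd.to_numeric(age_raw, errors="coerce")
        out["age_unit"] = raw.get("age_cod", pd.Series("", index=raw.index)).str.upper()
        out["age_years"] = [
            age_in_years(v if v == v else None, u)
            for v, u in zip(out["age_value"], out["age_unit"])
        ]
        out["age_years"] = pd.to_numeric(out["age_years"], errors="coerce")
        out["sex"] = raw.get("sex", pd.Series("", index=raw.index)).map(_map_sex)
        out["reporter"] = raw.get("occp_cod", pd.Series("", index=raw.index)).map(_map_reporter)
        out["country"] = raw.get("reporter_country", pd.Series("", index=raw.index)).str.upper()
        out["region"] = out["country"].map(to_region)
    elif kind == "DRUG":
        out["drug_seq"] = raw["drug_seq"].astype(int)
        out["role"] = raw["role_cod"].str.upper()
        out["raw_name"] = raw["drugname"]
        out["dose_amount"] = pd.to_numeric(
            raw.get("dose_amt", pd.Series("", index=raw.index)), errors="coerce")
        out["dose_unit"] = raw.get("dose_unit", pd.Series("", index=raw.index))
        out["dose_frequency"] = raw.get("dose_freq", pd.Series("", index=raw.index))
    elif kind == "REAC":
        out["pt"] = raw["pt"].map(lambda s: " ".join(s.split()))
    elif kind == "OUTC":
        out["outcome"] = raw["outc_cod"].str.upper()
    elif kind == "THER":
        out["dsg_drug_seq"] = raw["dsg_drug_seq"].astype(int)
        out["start_dt"] = raw.get("start_dt", pd.Series("", index=raw.index)).map(_clean_date_digits)
    return out[cols]


def read_database(directory: Union[str, Path]):
    """Read the five FAERS tables ``DEMO/DRUG/REAC/OUTC/THER`` from a directory.

    Files are located as ``<KIND>*.txt`` (case-insensitive prefix match).
    Returns ``(tables, reports)`` dicts keyed by table kind.
    """
    directory = Path(directory)
    tables, reports = {}, {}
    for kind in TABLE_KINDS:
        matches = sorted(p for p in directory.iterdir()
                         if p.name.upper().startswith(kind) and p.suffix.lower() == ".txt")
        if not matches:
            raise FileNotFoundError(f"no {kind}*.txt file in {directory}")
        frames = []
        report = IngestReport(table_kind=kind)
        for path in matches:
            frame, rep = read_table(path, kind)
            frames.append(frame)
            report.n_rows += rep.n_rows
            report.n_accepted += rep.n_accepted
            report.n_rejected += rep.n_rejected
            report.reject_reasons.update(rep.reject_reasons)
        tables[kind] = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
        reports[kind] = report
    return tables, reports


def iter_records(frame: pd.DataFrame, kind: str) -> Iterator:
    """Yield typed records (``DemoRecord`` etc.) from a validated frame."""
    kind = kind.upper()
    for row in frame.itertuples(index=False):
        if kind == "DEMO":
            yield DemoRecord(
                primaryid=row.primaryid, caseid=row.caseid,
                fda_dt=parse_partial_date(row.fda_dt),
                event_dt=parse_partial_date(row.event_dt),
                age_value=None if row.age_value != row.age_value else float(row.age_value),
                age_unit=row.age_unit or None,
                age_years=None if row.age_years != row.age_years else float(row.age_years),
                sex=row.sex, reporter=row.reporter,
                country=row.country or None, region=row.region)
        elif kind == "DRUG":
            yield DrugEntry(
                primaryid=row.primaryid, drug_seq=int(row.drug_seq),
                role=row.role, raw_name=row.raw_name,
                dose_amount=None if row.dose_amount != row.dose_amount else float(row.dose_amount),
                dose_unit=row.dose_unit or None,
                dose_frequency=row.dose_frequency or None)
        elif kind == "REAC":
            yield ReacEntry(primaryid=row.primaryid, pt=row.pt)
        elif kind == "OUTC":
            yield OutcEntry(primaryid=row.primaryid, outcome=row.outcome)
        elif kind == "THER":
            yield TherEntry(primaryid=row.primaryid,
                            dsg_drug_seq=int(row.dsg_drug_seq),
                            start_dt=parse_partial_date(row.start_dt))
        else:
            raise ValueError(f"unknown table kind {kind!r}")


# ---------------------------------------------------------------------------
# Writing FAERS-style tables (used by the synthetic generator) and results
# ---------------------------------------------------------------------------

_FAERS_HEADERS = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod", "reporter_country"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "dose_amt",
             "dose_unit", "dose_freq"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
}


def write_faers_tables(tables: dict, directory: Union[str, Path]) -> dict:
    """Write raw-format tables as ``<KIND>.txt`` "$"-delimited files.

    ``tables`` maps table kind to a DataFrame whose columns are the raw
    FAERS headers (see ``_FAERS_HEADERS``).  Returns {kind: path}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, frame in tables.items():
        header = _FAERS_HEADERS[kind.upper()]
        path = directory / f"{kind.upper()}.txt"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("$".join(header) + "\n")
            for row in frame[header].itertuples(index=False):
                fh.write("$".join("" if v is None or v != v else str(v)
                                  for v in row) + "\n")
        paths[kind.upper()] = path
    return paths


def write_results(tables: dict, destination: Union[str, Path],
                  metadata: Optional[dict] = None) -> dict:
    """Write result tables as CSVs plus a JSON run-metadata file.

    ``tables`` maps a logical name (e.g. ``signals``) to a DataFrame.  The
    write is deterministic: identical inputs reproduce byte-identical files.
    Returns a manifest {name: {path, sha256, n_rows}}.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, frame in tables.items():
        path = destination / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[name] = {"path": str(path), "sha256": digest,
                          "n_rows": int(len(frame))}
    meta = dict(metadata or {})
    meta["tables"] = {k: {"sha256": v["sha256"], "n_rows": v["n_rows"]}
                      for k, v in manifest.items()}
    meta_path = destination / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True,
                                    default=str) + "\n")
    manifest["run_metadata"] = {"path": str(meta_path)}
    return manifest
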