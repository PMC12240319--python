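"""DILI cohort construction.

A deduplicated case is classified as drug-induced liver injury (DILI) when
at least one of its reported Preferred Terms belongs to the hepatic SMQ
term set (SMQ 20000007, narrow scope); however many SMQ terms matched, the
case contributes exactly one DILI record.  Cases whose therapy start date
is strictly later than the event date are excluded: a liver event that
predates the suspect drug cannot have been induced by it.

The module assembles one row per retained case ("case report") carrying the
primary-suspect statin set, DILI flag, demographics, outcomes and the dates
needed for the time-to-onset analysis, and keeps non-statin cases in the
same universe frame so they can serve as the disproportionality comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterator, Optional, Set, Tuple, Union

import numpy as np
import pandas as pd

from .drug_map import DrugDictionary, select_primary_suspect
from .faers_io import PartialDate, compare_partial, parse_partial_date

#: Severity order used to pick one outcome per case (FAERS convention:
#: a case reporting both death and hospitalization counts as a death).
OUTCOME_SEVERITY = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Daily-frequency multipliers for dose normalization; blank frequency is
#: read as once daily (the overwhelmingly common FAERS default).
DOSE_FREQ_PER_DAY = {
    "": 1.0, "QD": 1.0, "DAILY": 1.0, "QDAY": 1.0, "HS": 1.0,
    "BID": 2.0, "TID": 3.0, "QID": 4.0,
    "QOD": 0.5, "QW": 1.0 / 7.0, "WEEKLY": 1.0 / 7.0, "Q2W": 1.0 / 14.0,
}


def normalize_pt(pt: str) -> str:
    """Whitespace-collapsed, case-folded form used for PT matching."""
    return " ".join(str(pt).split()).upper()


@dataclass(frozen=True)
class SmqTermSet:
    """The Preferred Terms defining the DILI event (narrow-scope SMQ)."""

    terms: FrozenSet[str]
    smq_code: str = "20000007"
    scope: str = "narrow"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("empty SMQ term set")

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.terms


def load_smq_terms(path: Optional[Union[str, Path]] = None) -> SmqTermSet:
    """Load an SMQ PT list (one PT per line, ``#`` comments).

    Without ``path`` the packaged synthetic stand-in list is used; MedDRA
    license holders should point this at the authoritative narrow-scope
    list for SMQ 20000007.
    """
    if path is None:
        src = resources.files("faers_dili.data").joinpath(
            "smq_dili_narrow_synthetic.txt")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    terms = {normalize_pt(ln) for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")}
    return SmqTermSet(terms=frozenset(terms))


def classify_dili(pts_of_case: Set[str], smq: SmqTermSet
                  ) -> Tuple[bool, FrozenSet[str]]:
    """DILI flag and the matching PTs for one case's Preferred Terms."""
    if not smq.terms:
        raise ValueError("empty SMQ term set")
    matched = frozenset(normalize_pt(p) for p in pts_of_case) & smq.terms
    return bool(matched), matched


def temporal_exclusion(event_dt: Optional[PartialDate],
                       start_dt: Optional[PartialDate]) -> str:
    """``"exclude"`` when therapy start is strictly later than the event.

    Dates are compared at their coarsest common precision; a missing date
    or a tie never excludes (conservative reading of "later than").
    """
    cmp = compare_partial(start_dt, event_dt)
    return "exclude" if cmp is not None and cmp > 0 else "keep"


@dataclass(frozen=True)
class CaseReport:
    """One retained, deduplicated case."""

    caseid: str
    primaryid: str
    statins: FrozenSet[str]
    is_dili: bool
    matched_pts: FrozenSet[str]
    age_years: Optional[float]
    age_group: str
    sex: str
    reporter: str
    region: str
    outcomes: FrozenSet[str]
    worst_outcome: str
    event_dt: Optional[PartialDate]
    earliest_start_dt: Optional[PartialDate]
    doses_mg_per_day: Dict[str, float]
    receipt_year: int


@dataclass
class CohortResult:
    """Assembled study universe plus the statin DILI/non-DILI partition.

    ``universe`` holds every retained case (statin or comparator) with its
    DILI flag; ``dili``/``non_dili`` are the statin-exposed partition used
    by the descriptive tables.
    """

    universe: pd.DataFrame
    exclusion: dict = field(default_factory=dict)

    @property
    def statin_cases(self) -> pd.DataFrame:
        return self.universe[self.universe["statins"].map(bool)]

    @property
    def dili(self) -> pd.DataFrame:
        s = self.statin_cases
        return s[s["is_dili"]]

    @property
    def non_dili(self) -> pd.DataFrame:
        s = self.statin_cases
        return s[~s["is_dili"]]

    def case_reports(self) -> Iterator[CaseReport]:
        for row in self.statin_cases.itertuples(index=False):
            yield CaseReport(
                caseid=row.caseid, primaryid=row.primaryid,
                statins=frozenset(row.statins), is_dili=bool(row.is_dili),
                matched_pts=frozenset(row.matched_pts),
                age_years=None if row.age_years != row.age_years else float(row.age_years),
                age_group=row.age_group, sex=row.sex, reporter=row.reporter,
                region=row.region, outcomes=frozenset(row.outcomes),
                worst_outcome=row.worst_outcome,
                event_dt=parse_partial_date(row.event_dt),
                earliest_start_dt=parse_partial_date(row.earliest_start_dt),
                doses_mg_per_day=dict(row.doses_mg_per_day),
                receipt_year=int(row.receipt_year))


def age_group_of(age_years: float) -> str:
    """Table-1 age grouping; the boundary value 65.0 falls in the elderly group."""
    if age_years != age_years:  # NaN
        return "unknown"
    return ">=65" if age_years >= 65.0 else "<65"


def dose_per_day_mg(amount, unit, frequency) -> float:
    """Daily dose in mg, NaN when the unit is not mg or amount is missing."""
    if amount is None or amount != amount:
        return float("nan")
    if str(unit or "").strip().upper() != "MG":
        return float("nan")
    mult = DOSE_FREQ_PER_DAY.get(str(frequency or "").strip().upper())
    if mult is None:
        return float("nan")
    return float(amount) * mult


def _min_start_digits(digit_strings) -> str:
    """Earliest of several partial start dates (by zero-padded comparison)."""
    best = ""
    best_key = None
    for d in digit_strings:
        if not d:
            continue
        key = d.ljust(8, "0")
        if best_key is None or key < best_key:
            best, best_key = d, key
    return best


def assemble_cohort(demo: pd.DataFrame, drug: pd.DataFrame,
                    reac: pd.DataFrame, outc: pd.DataFrame,
                    ther: pd.DataFrame, dictionary: DrugDictionary,
                    smq: SmqTermSet) -> CohortResult:
    """Build the study universe from deduplicated tables.

    Every DEMO case is retained unless it fails the temporal rule; cases
    without a PS statin stay in the universe as comparator reports with an
    empty statin set.  Returns a :class:`CohortResult`.
    """
    if not smq.terms:
        raise ValueError("empty SMQ term set")

    ps, mapping_report = select_primary_suspect(drug, dictionary)

    # statin sets and per-statin daily doses
    statin_sets: Dict[str, frozenset] = {}
    dose_maps: Dict[str, dict] = {}
    ps_seqs: Dict[str, set] = {}
    for row in ps.itertuples(index=False):
        statin_sets.setdefault(row.primaryid, set()).add(row.generic)  # type: ignore[union-attr]
        ps_seqs.setdefault(row.primaryid, set()).add(int(row.drug_seq))
        mg = dose_per_day_mg(row.dose_amount, row.dose_unit, row.dose_frequency)
        if mg == mg:
            dose_maps.setdefault(row.primaryid, {})[row.generic] = mg

    # DILI classification per case
    pt_norm = reac["pt"].map(normalize_pt)
    is_smq = pt_norm.isin(smq.terms)
    matched_by_pid = (
        pt_norm[is_smq].groupby(reac.loc[is_smq, "primaryid"]).agg(frozenset)
        if is_smq.any() else pd.Series(dtype=object))

    # one outcome per case by severity priority
    severity_rank = {code: i for i, code in enumerate(OUTCOME_SEVERITY)}
    outcome_sets = outc.groupby("primaryid")["outcome"].agg(frozenset) \
        if len(outc) else pd.Series(dtype=object)

    # earliest therapy start: prefer THER rows linked to the PS statin's
    # drug_seq, fall back to any THER row of the case
    start_by_pid: Dict[str, str] = {}
    if len(ther):
        for pid, grp in ther.groupby("primaryid"):
            seqs = ps_seqs.get(pid)
            linked = grp[grp["dsg_drug_seq"].isin(seqs)] if seqs else grp.iloc[0:0]
            chosen = _min_start_digits(linked["start_dt"])
            if not chosen:
                chosen = _min_start_digits(grp["start_dt"])
            if chosen:
                start_by_pid[pid] = chosen

    uni = demo.copy()
    uni["statins"] = [frozenset(statin_sets.get(pid, ())) for pid in uni["primaryid"]]
    uni["matched_pts"] = [matched_by_pid.get(pid, frozenset()) for pid in uni["primaryid"]]
    uni["is_dili"] = uni["matched_pts"].map(bool)
    uni["outcomes"] = [outcome_sets.get(pid, frozenset()) for pid in uni["primaryid"]]
    uni["worst_outcome"] = uni["outcomes"].map(
        lambda s: min(s, key=severity_rank.get) if s else "unknown")
    uni["earliest_start_dt"] = [start_by_pid.get(pid, "") for pid in uni["primaryid"]]
    uni["doses_mg_per_day"] = [dose_maps.get(pid, {}) for pid in uni["primaryid"]]
    uni["age_group"] = uni["age_years"].map(age_group_of)
    uni["receipt_year"] = [int(d[:4]) if d else -1 for d in uni["fda_dt"]]

    decisions = [
        temporal_exclusion(parse_partial_date(e), parse_partial_date(s))
        for e, s in zip(uni["event_dt"], uni["earliest_start_dt"])
    ]
    keep_mask = np.array([d == "keep" for d in decisions])
    n_excluded = int((~keep_mask).sum())
    retained = uni[keep_mask].reset_index(drop=True)

    n_statin = int(retained["statins"].map(bool).sum())
    result = CohortResult(
        universe=retained,
        exclusion={
            "n_input_cases": int(len(demo)),
            "n_excluded_temporal": n_excluded,
            "n_retained": int(len(retained)),
            "n_statin_cases": n_statin,
            "n_background_cases": int(len(retained)) - n_statin,
            "n_dili_statin": int(retained["is_dili"][retained["statins"].map(bool)].sum()),
            "mapping": mapping_report.as_dict(),
        },
    )
    result.exclusion["n_non_dili_statin"] = (
        result.exclusion["n_statin_cases"] - result.exclusion["n_dili_statin"])
    return result
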