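"""Case-level deduplication of FAERS report versions.

A FAERS case (CASEID) can be submitted several times; each submission gets
its own PRIMARYID.  Following the FDA-recommended rule, one record per case
is retained: the version with the latest FDA receipt date (FDA_DT), ties
broken by the numerically higher PRIMARYID.

FDA_DT values may carry year/month/day precision.  Within one case group
all dates are compared after truncation to the group's coarsest reported
precision (missing dates sort lowest); this makes the survivor the maximum
of a total order, so the result cannot depend on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd


class CorruptInputError(ValueError):
    """The same PRIMARYID appears under different CASEIDs."""


@dataclass
class DedupReport:
    n_input: int = 0
    n_cases: int = 0
    n_removed: int = 0
    removed_primaryids: list = field(default_factory=list)
    #: caseids whose report versions carried FDA_DT at differing precisions;
    #: for these the survivor was chosen at the group's coarsest precision.
    mixed_precision_caseids: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_cases": self.n_cases,
            "n_removed": self.n_removed,
            "n_mixed_precision_cases": len(self.mixed_precision_caseids),
        }


def _primaryid_sort_key(pids: pd.Series) -> pd.Series:
    """Total ordering for PRIMARYIDs.

    Numeric comparison when every id parses as an integer; otherwise
    lexicographic after left-zero-padding to a common length.
    """
    stripped = pids.astype(str).str.strip()
    if stripped.str.isdigit().all():
        return stripped.astype(np.int64)
    width = int(stripped.str.len().max())
    return stripped.str.zfill(width)


def dedupe_cases(demo: pd.DataFrame,
                 linked_tables: Optional[Dict[str, pd.DataFrame]] = None
                 ) -> Tuple[pd.DataFrame, Optional[Dict[str, pd.DataFrame]], DedupReport]:
    """Collapse DEMO report versions to one record per CASEID.

    Parameters
    ----------
    demo
        Validated DEMO frame (``faers_io.read_table``).
    linked_tables
        Optional {kind: frame} of DRUG/REAC/OUTC/THER tables; rows belonging
        to removed PRIMARYIDs are dropped in the same pass.

    Returns
    -------
    (survivors, filtered_linked_tables, report)
    """
    report = DedupReport(n_input=len(demo))
    if demo.empty:
        report.n_cases = 0
        return demo.copy(), linked_tables, report

    # a PRIMARYID pointing at two different cases is corrupt input
    pid_cases = demo.groupby("primaryid")["caseid"].nunique()
    bad = pid_cases[pid_cases > 1]
    if len(bad):
        raise CorruptInputError(
            f"primaryid(s) shared across caseids: {list(bad.index[:5])}")

    work = demo[["primaryid", "caseid", "fda_dt"]].copy()
    # drop exact re-listings of the same report version
    work = work.drop_duplicates(subset="primaryid")

    digits = work["fda_dt"].fillna("").astype(str)
    prec = digits.str.len()  # 0, 4, 6 or 8
    # coarsest reported precision within each case group (missing ignored)
    group_prec = prec.where(prec > 0).groupby(work["caseid"]).transform("min")
    group_prec = group_prec.fillna(0).astype(int)
    truncated = [d[:n] if n else "" for d, n in zip(digits, group_prec)]
    has_date = prec > 0
    date_key = pd.Series([int(t) if t else -1 for t in truncated],
                         index=work.index)
    pid_key = _primaryid_sort_key(work["primaryid"])

    order = pd.DataFrame({
        "caseid": work["caseid"],
        "has_date": has_date.astype(int),
        "date_key": date_key,
        "pid_key": pid_key,
        "primaryid": work["primaryid"],
    }).sort_values(["caseid", "has_date", "date_key", "pid_key"],
                   kind="mergesort")
    survivors_pid = order.groupby("caseid", sort=False)["primaryid"].last()

    n_prec = prec.where(prec > 0).groupby(work["caseid"]).nunique()
    report.mixed_precision_caseids = sorted(n_prec[n_prec > 1].index)

    keep = set(survivors_pid)
    survivors = demo[demo["primaryid"].isin(keep)].drop_duplicates(
        subset="primaryid").reset_index(drop=True)
    removed = demo.loc[~demo["primaryid"].isin(keep), "primaryid"]
    report.removed_primaryids = sorted(set(removed))
    report.n_removed = len(report.removed_primaryids)
    report.n_cases = len(survivors)

    filtered = None
    if linked_tables is not None:
        filtered = {
            kind: frame[frame["primaryid"].isin(keep)].reset_index(drop=True)
            for kind, frame in linked_tables.items()
        }
    return survivors, filtered, report
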