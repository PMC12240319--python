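"""Descriptive rollups, group comparisons, dose trend and time-to-onset.

Produces the demographic/outcome frequency tables (DILI vs non-DILI
columns with half-up two-decimal percentages), Pearson chi-square
comparisons, the dose-group trend for atorvastatin, annual report counts
and the per-drug time-to-onset summary (median/IQR with a one-way ANOVA
and uncorrected pairwise Welch tests across drugs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OUTCOME_SEVERITY
from .drug_map import STATINS
from .faers_io import REGIONS, PartialDate, parse_partial_date

OUTCOME_LABELS = {
    "DE": "Death", "LT": "Life threatening", "HO": "Hospitalization",
    "DS": "Disability", "CA": "Congenital anomaly",
    "RI": "Required intervention", "OT": "Other serious events",
    "unknown": "Unknown",
}


def proportion(numerator: int, denominator: int) -> float:
    """Percentage with half-up rounding to two decimals; NaN for 0 denominator."""
    if denominator == 0:
        return math.nan
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class FreqTable:
    """Category counts per group with percentages against group totals."""

    characteristic: str
    counts: pd.DataFrame  # index: category labels, columns: group labels
    denominators: Dict[str, int]

    def percentages(self) -> pd.DataFrame:
        out = self.counts.copy().astype(float)
        for col in out.columns:
            den = self.denominators[col]
            out[col] = [proportion(int(v), den) if den else math.nan
                        for v in self.counts[col]]
        return out

    def tidy(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = []
        for cat in self.counts.index:
            row = {"characteristic": self.characteristic, "category": cat}
            for col in self.counts.columns:
                row[f"{col}_n"] = int(self.counts.loc[cat, col])
                row[f"{col}_pct"] = pct.loc[cat, col]
            rows.append(row)
        return pd.DataFrame(rows)


def _count_by(cases: pd.DataFrame, key, categories: Sequence[str]) -> pd.Series:
    vals = cases[key] if isinstance(key, str) else key(cases)
    counts = vals.value_counts()
    return pd.Series([int(counts.get(c, 0)) for c in categories],
                     index=list(categories))


def demographics_table(dili: pd.DataFrame, non_dili: pd.DataFrame
                       ) -> Dict[str, FreqTable]:
    """Demographic and outcome frequency tables, DILI vs non-DILI columns.

    Categories mirror the standard pharmacovigilance case-characteristics
    layout: per-statin counts (a case with several PS statins counts once
    per statin), age groups, sex, one severity-ranked outcome per case,
    reporter type and reporter region.  Unknown rows are always present.
    """
    groups = {"dili": dili, "non_dili": non_dili}
    dens = {g: len(df) for g, df in groups.items()}
    tables: Dict[str, FreqTable] = {}

    def build(name: str, categories: Sequence[str], getter) -> None:
        counts = pd.DataFrame({g: _count_by(df, getter, categories)
                               for g, df in groups.items()})
        tables[name] = FreqTable(name, counts, dict(dens))

    build("statin", list(STATINS),
          lambda df: df["statins"].explode() if len(df) else pd.Series(dtype=object))
    build("age_group", ["<65", ">=65", "unknown"], "age_group")
    build("sex", ["female", "male", "unknown"], "sex")
    build("outcomes",
          [OUTCOME_LABELS[c] for c in (*OUTCOME_SEVERITY, "unknown")],
          lambda df: df["worst_outcome"].map(OUTCOME_LABELS))
    build("reporter", ["health_professional", "non_health_professional",
                       "unknown"], "reporter")
    build("region", list(REGIONS), "region")
    return tables


def chi_square(counts) -> Tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    ``counts`` is any r x c array of nonnegative counts; all-zero rows and
    columns are dropped first.  A zero expected cell is a hard error.
    """
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0] if arr.ndim == 2 else arr
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zeros")
    expected = stats.contingency.expected_freq(arr)
    if (expected == 0).any():
        i, j = np.argwhere(expected == 0)[0]
        raise ValueError(f"expected count is zero in cell ({i}, {j})")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class DoseTrendResult:
    drug: str
    counts: pd.Series  # index: dose (mg/day)
    n_excluded: int
    heterogeneity_chi2: float
    heterogeneity_p: float
    trend_z: float
    trend_p: float

    @property
    def defined(self) -> bool:
        return self.trend_z == self.trend_z


def dose_trend(dili_cases: pd.DataFrame, drug: str = "atorvastatin",
               doses: Sequence[float] = (10.0, 20.0, 40.0, 80.0)
               ) -> DoseTrendResult:
    """Case counts per daily-dose group with heterogeneity and trend tests.

    Input are DILI cases; a case contributes when its PS dose for ``drug``
    parses to one of the listed daily-mg groups, others are excluded and
    counted.  The trend statistic is a multinomial linear-trend z-score on
    rank scores (0 for flat counts, large for monotone gradients), reported
    alongside the equal-frequency heterogeneity chi-square.
    """
    on_drug = dili_cases[dili_cases["statins"].map(lambda s: drug in s)]
    mg = on_drug["doses_mg_per_day"].map(lambda m: m.get(drug, math.nan))
    counts = pd.Series(0, index=list(doses), dtype=int)
    n_excluded = 0
    for v in mg:
        if v == v and v in counts.index:
            counts[v] += 1
        else:
            n_excluded += 1
    total = int(counts.sum())
    if (counts == 0).any() or total == 0:
        return DoseTrendResult(drug, counts, n_excluded, math.nan, math.nan,
                               math.nan, math.nan)
    chi2_stat, chi2_p = stats.chisquare(counts.to_numpy())
    scores = np.arange(len(doses), dtype=float)
    s_bar = scores.mean()
    var = total * (np.mean(scores ** 2) - s_bar ** 2)
    t_obs = float((counts.to_numpy() * scores).sum())
    z = (t_obs - total * s_bar) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DoseTrendResult(drug, counts, n_excluded, float(chi2_stat),
                           float(chi2_p), float(z), float(p))


def onset_days(event_dt: Optional[PartialDate],
               start_dt: Optional[PartialDate]) -> Optional[int]:
    """Days from therapy start to event; needs day precision on both dates.

    Returns ``None`` (case excluded from the onset analysis) when either
    date is missing or coarser than day precision, or the difference is
    negative.
    """
    if event_dt is None or start_dt is None:
        return None
    if event_dt.precision != "day" or start_dt.precision != "day":
        return None
    delta = (event_dt.to_date() - start_dt.to_date()).days
    return delta if delta >= 0 else None


def onset_samples(dili_cases: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Per (case, statin) onset samples; cases without usable dates counted.

    Returns (frame with columns ``drug, onset_days``, n_excluded).
    """
    rows: List[dict] = []
    n_excluded = 0
    for row in dili_cases.itertuples(index=False):
        days = onset_days(parse_partial_date(row.event_dt),
                          parse_partial_date(row.earliest_start_dt))
        if days is None:
            n_excluded += 1
            continue
        for drug in sorted(row.statins):
            rows.append({"drug": drug, "onset_days": days})
    return pd.DataFrame(rows, columns=["drug", "onset_days"]), n_excluded


def onset_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-drug (n, median, IQR) plus an overall row.

    Quantiles use the linear-interpolation convention; drugs with no
    samples are absent.
    """
    def _row(name: str, vals: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"drug": name, "n": int(len(vals)), "median_days": float(med),
                "iqr_low": float(q1), "iqr_high": float(q3)}

    rows = [_row(drug, grp["onset_days"].to_numpy(float))
            for drug, grp in samples.groupby("drug")] if len(samples) else []
    if len(samples):
        rows.append(_row("overall", samples["onset_days"].to_numpy(float)))
    return pd.DataFrame(rows, columns=["drug", "n", "median_days",
                                       "iqr_low", "iqr_high"])


@dataclass
class OnsetComparison:
    method: str
    statistic: float
    p_value: float
    groups: List[str]
    dropped_groups: List[str] = field(default_factory=list)
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def defined(self) -> bool:
        return self.p_value == self.p_value


def compare_onset(samples: pd.DataFrame, method: str = "anova",
                  flag_level: float = 0.05) -> OnsetComparison:
    """Compare onset-time distributions across drugs.

    Overall test: one-way ANOVA (``method="anova"``, the conventional
    choice for this analysis despite the skew of latency data) or
    Kruskal-Wallis (``method="kruskal"``, rank-based alternative).
    Pairwise: Welch two-sample t-tests, uncorrected, with pairs below
    ``flag_level`` flagged.  Groups with fewer than 2 samples are dropped
    with a note; fewer than 2 usable groups yields NaN statistics.
    """
    if method not in ("anova", "kruskal"):
        raise ValueError(f"unknown method {method!r}")
    groups, dropped = {}, []
    for drug, grp in samples.groupby("drug"):
        vals = grp["onset_days"].to_numpy(float)
        if len(vals) >= 2:
            groups[drug] = vals
        else:
            dropped.append(drug)
    names = sorted(groups)
    if len(names) < 2:
        return OnsetComparison(method, math.nan, math.nan, names, dropped)
    arrays = [groups[n] for n in names]
    if method == "anova":
        stat, p = stats.f_oneway(*arrays)
    else:
        stat, p = stats.kruskal(*arrays)
    pairs = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            t, pij = stats.ttest_ind(groups[gi], groups[gj], equal_var=False)
            pairs.append({"drug_1": gi, "drug_2": gj, "t": float(t),
                          "p": float(pij), "flagged": bool(pij < flag_level)})
    return OnsetComparison(method, float(stat), float(p), names, dropped,
                           pd.DataFrame(pairs, columns=["drug_1", "drug_2",
                                                        "t", "p", "flagged"]))


def annual_counts(statin_cases: pd.DataFrame,
                  year_range: Tuple[int, int] = (2004, 2023)) -> pd.DataFrame:
    """Per-year DILI and non-DILI statin case counts over the full range.

    Years without reports are emitted with zeros.
    """
    lo, hi = year_range
    years = list(range(lo, hi + 1))
    dili_y = statin_cases.loc[statin_cases["is_dili"], "receipt_year"].value_counts()
    non_y = statin_cases.loc[~statin_cases["is_dili"], "receipt_year"].value_counts()
    return pd.DataFrame({
        "year": years,
        "dili": [int(dili_y.get(y, 0)) for y in years],
        "non_dili": [int(non_y.get(y, 0)) for y in years],
    })
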