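"""Disproportionality statistics: reporting odds ratio and information component.

For a target drug the spontaneous-report database is collapsed to a 2x2
table — a: target drug & DILI, b: target drug & other events, c: comparator
& DILI, d: comparator & other events — where the comparator is every loaded
case not exposed to the target as primary suspect.  Two measures are
computed:

* ROR = (a/b)/(c/d) with the Woolf (log-scale) 95% confidence interval
  ``exp(ln ROR +- 1.96*sqrt(1/a + 1/b + 1/c + 1/d))``, no continuity
  correction.
* IC = log2 of observed over expected target-DILI reports under
  independence, ``log2(a*N / ((a+b)*(a+c)))``.  Credibility bounds use the
  Noren asymmetric approximation by default, or an analytic Gamma-posterior
  quantile alternative.

A drug-event pair is called a signal only when BOTH rules fire: the ROR
rule (at least 3 cases and CI lower limit > 1) and the IC rule (IC > 1 and
credibility lower bound > 0).  Any undefined quantity (zero cells) fails
the corresponding rule; no Haldane correction is applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile

IC_CI_METHODS = ("noren", "gamma")


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells of one drug-vs-database 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected target-DILI count under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class BackgroundOdds:
    """Comparator DILI odds q = c/d and proportion p = q/(1+q)."""

    q: float

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError("background odds must be positive")

    @property
    def p(self) -> float:
        return self.q / (1.0 + self.q)


@dataclass(frozen=True)
class SignalResult:
    drug: str
    table: ContingencyTable
    ror: float
    ror_l: float
    ror_u: float
    ic: float
    ic_l: float
    ic_u: float
    ror_signal: bool
    ic_signal: bool
    signal: bool
    ic_ci_method: str = "noren"
    stratum: Optional[str] = None

    @property
    def n_cases(self) -> int:
        return self.table.a


def build_contingency(universe: pd.DataFrame, drug: str) -> ContingencyTable:
    """Collapse the case universe to the 2x2 table for ``drug``.

    A case counts on the target side when ``drug`` is among its PS statins;
    every other case (other statins and background drugs alike) is
    comparator.  ``universe`` needs columns ``statins`` (set-like) and
    ``is_dili`` (bool).
    """
    if universe.empty:
        raise ValueError("empty universe")
    on_target = universe["statins"].map(lambda s: drug in s).to_numpy(bool)
    dili = universe["is_dili"].to_numpy(bool)
    a = int((on_target & dili).sum())
    b = int((on_target & ~dili).sum())
    c = int((~on_target & dili).sum())
    d = int((~on_target & ~dili).sum())
    return ContingencyTable(a, b, c, d)


def ror_estimate(t: ContingencyTable) -> Tuple[float, float, float]:
    """ROR point estimate and Woolf 95% CI; NaN triple on any zero cell."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a / t.b) / (t.c / t.d)
    half = Z95 * math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, ror * math.exp(-half), ror * math.exp(half))


def ic_estimate(t: ContingencyTable, ci_method: str = "noren",
                shrinkage: bool = False) -> Tuple[float, float, float]:
    """Information component point estimate and 95% credibility bounds.

    The point estimate is the plain observed/expected log2 ratio; with
    ``shrinkage=True`` the BCPNN-style +0.5 continuity terms are applied to
    both numerator and denominator instead.  Bounds per ``ci_method``:
    ``"noren"`` (asymmetric series approximation around the shrunk
    estimate) or ``"gamma"`` (analytic Gamma-posterior quantiles).
    Returns a NaN triple when a = 0 (undefined).
    """
    if ci_method not in IC_CI_METHODS:
        raise ValueError(f"unknown IC interval method {ci_method!r}")
    if t.a == 0:
        return (math.nan, math.nan, math.nan)
    expected = t.expected_a
    if expected <= 0:
        return (math.nan, math.nan, math.nan)
    if shrinkage:
        ic = math.log2((t.a + 0.5) / (expected + 0.5))
    else:
        ic = math.log2(t.a / expected)
    if ci_method == "noren":
        s = t.a + 0.5
        ic_l = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
        ic_u = ic + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
    else:  # gamma
        ic_l = math.log2(stats.gamma.ppf(0.025, t.a + 0.5) / (expected + 0.5))
        ic_u = math.log2(stats.gamma.ppf(0.975, t.a + 0.5) / (expected + 0.5))
    return (ic, ic_l, ic_u)


def classify_signal(drug: str, t: ContingencyTable,
                    ror_triple: Tuple[float, float, float],
                    ic_triple: Tuple[float, float, float],
                    ic_ci_method: str = "noren",
                    stratum: Optional[str] = None) -> SignalResult:
    """Apply the dual signal criteria to precomputed estimates.

    ROR rule: at least 3 target-DILI cases and CI lower limit > 1.
    IC rule: IC > 1 and credibility lower bound > 0.  NaN (undefined)
    quantities fail their rule.
    """
    ror, ror_l, ror_u = ror_triple
    ic, ic_l, ic_u = ic_triple
    ror_signal = bool(t.a >= 3 and ror_l == ror_l and ror_l > 1.0)
    ic_signal = bool(ic == ic and ic > 1.0 and ic_l == ic_l and ic_l > 0.0)
    return SignalResult(drug=drug, table=t, ror=ror, ror_l=ror_l, ror_u=ror_u,
                        ic=ic, ic_l=ic_l, ic_u=ic_u, ror_signal=ror_signal,
                        ic_signal=ic_signal, signal=ror_signal and ic_signal,
                        ic_ci_method=ic_ci_method, stratum=stratum)


def compute_signal(universe: pd.DataFrame, drug: str,
                   ic_ci_method: str = "noren",
                   stratum: Optional[str] = None) -> SignalResult:
    """Build the table for ``drug`` and evaluate both measures and the rules."""
    t = build_contingency(universe, drug)
    return classify_signal(drug, t, ror_estimate(t),
                           ic_estimate(t, ci_method=ic_ci_method),
                           ic_ci_method=ic_ci_method, stratum=stratum)


def compute_signals(universe: pd.DataFrame, drugs: Sequence[str],
                    ic_ci_method: str = "noren") -> List[SignalResult]:
    return [compute_signal(universe, d, ic_ci_method=ic_ci_method)
            for d in drugs]


def stratified_signals(universe: pd.DataFrame, drug: str,
                       ic_ci_method: str = "noren") -> List[SignalResult]:
    """Age-stratified signals ("<65" vs ">=65").

    Unknown-age cases are excluded from both strata (they remain in the
    overall analysis); the comparator is restricted to the same stratum.
    An empty stratum yields no result for that label.
    """
    results = []
    for label in ("<65", ">=65"):
        sub = universe[universe["age_group"] == label]
        if sub.empty:
            continue
        results.append(compute_signal(sub, drug, ic_ci_method=ic_ci_method,
                                      stratum=label))
    return results


def recover_background(printed: Dict[str, Tuple[int, int, float]],
                       holdout: Optional[str] = None) -> BackgroundOdds:
    """Recover the unprinted comparator odds from published per-drug rows.

    Published signal tables print each drug's DILI count ``a``, non-DILI
    count ``b`` and ROR but not the comparator cells.  Each row implies
    ``q_i = (a_i/b_i)/ROR_i``; the single q minimizing the sum of squared
    relative errors between ``(a_i/b_i)/q`` and the printed RORs has the
    closed form ``q = sum(q_i^2)/sum(q_i)``.

    ``printed`` maps drug -> (a, b, ror); ``holdout`` names a drug to leave
    out of the fit (for cross-prediction).
    """
    qs = []
    for name, (a, b, ror) in printed.items():
        if name == holdout:
            continue
        if b == 0:
            raise ValueError(f"degenerate printed row for {name}: b = 0")
        if ror <= 0 or a <= 0:
            raise ValueError(f"degenerate printed row for {name}")
        qs.append((a / b) / ror)
    if not qs:
        raise ValueError("no rows left to fit after holdout")
    qs_arr = np.asarray(qs)
    return BackgroundOdds(q=float((qs_arr ** 2).sum() / qs_arr.sum()))


def background_table(a: int, b: int, background: BackgroundOdds,
                     d: int = 10 ** 8) -> ContingencyTable:
    """A 2x2 table pairing printed (a, b) with a very large comparator.

    The comparator cells preserve the recovered odds ``q`` at size ``d``;
    with d >= 1e6 the 1/c + 1/d terms contribute negligibly to the Woolf
    interval, emulating a whole-database comparator.
    """
    c = int(round(background.q * d))
    return ContingencyTable(a, b, c, d)


def ror_from_background(a: int, b: int, background: BackgroundOdds) -> float:
    """ROR of printed counts (a, b) against the recovered comparator odds."""
    return (a / b) / background.q


def ic_from_background(a: int, b: int, background: BackgroundOdds) -> float:
    """IC of printed counts against the recovered comparator proportion.

    log2 of the drug's DILI proportion a/(a+b) over the comparator DILI
    proportion p; for a vanishing drug share of the database this equals
    the observed/expected IC.
    """
    return math.log2((a / (a + b)) / background.p)


def signals_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Flatten signal results to the ``signals.csv`` column layout."""
    rows = []
    for r in results:
        rows.append({
            "drug": r.drug, "stratum": r.stratum or "overall",
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": r.ror, "ror_l": r.ror_l, "ror_u": r.ror_u,
            "ic": r.ic, "ic_l": r.ic_l, "ic_u": r.ic_u,
            "n_cases": r.n_cases, "ror_signal": r.ror_signal,
            "ic_signal": r.ic_signal, "signal": r.signal,
            "ic_ci_method": r.ic_ci_method,
        })
    return pd.DataFrame(rows, columns=[
        "drug", "stratum", "a", "b", "c", "d", "ror", "ror_l", "ror_u",
        "ic", "ic_l", "ic_u", "n_cases", "ror_signal", "ic_signal",
        "signal", "ic_ci_method"])
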