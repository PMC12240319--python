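"""Standardization of raw drug-name strings to generic statin names.

FAERS drug names arrive as generics, trade names, salt forms and free-text
variants.  A curated dictionary (shipped as a CSV asset, user-extensible)
maps each variant to one of the eight WHO-ATC statins.  Lookup is by exact
normalized key — uppercased, whitespace-collapsed, trailing salt/hydrate
suffixes stripped — never by substring or fuzzy match, so the mapping is
fully deterministic and auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Set, Tuple, Union

import pandas as pd

#: The eight target statins with their WHO ATC codes.
STATIN_ATC = {
    "atorvastatin": "C10AA05",
    "cerivastatin": "C10AA06",
    "fluvastatin": "C10AA04",
    "lovastatin": "C10AA02",
    "pitavastatin": "C10AA08",
    "pravastatin": "C10AA03",
    "rosuvastatin": "C10AA07",
    "simvastatin": "C10AA01",
}

STATINS = tuple(sorted(STATIN_ATC))

#: Trailing tokens removed during key normalization (salt/hydrate forms).
SALT_SUFFIXES = {
    "CALCIUM", "SODIUM", "MAGNESIUM", "HEMICALCIUM",
    "TRIHYDRATE", "MONOHYDRATE", "DIHYDRATE", "ANHYDROUS",
}


def normalize_key(raw_name: str) -> str:
    """Normalize a raw drug-name string to its dictionary key."""
    tokens = str(raw_name).upper().split()
    while tokens and tokens[-1] in SALT_SUFFIXES:
        tokens.pop()
    return " ".join(tokens)


@dataclass(frozen=True)
class DrugDictionary:
    """Mapping from normalized raw-name keys to generic statin names."""

    entries: Dict[str, str]
    generics: Dict[str, str] = field(default_factory=lambda: dict(STATIN_ATC))

    def __post_init__(self) -> None:
        bad = {g for g in self.entries.values() if g not in self.generics}
        if bad:
            raise ValueError(f"dictionary maps to non-statin generics: {sorted(bad)}")

    def variants_of(self, generic: str) -> list:
        """All raw-name keys mapping to ``generic`` (useful for simulation)."""
        return sorted(k for k, g in self.entries.items() if g == generic)


def load_drug_dictionary(path: Optional[Union[str, Path]] = None) -> DrugDictionary:
    """Load the drug dictionary CSV (columns raw_name, generic, atc_code).

    Without ``path`` the packaged statin dictionary is used.
    """
    if path is None:
        with resources.files("faers_dili.data").joinpath("statin_dictionary.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    entries: Dict[str, str] = {}
    for raw, generic in zip(df["raw_name"], df["generic"]):
        key = normalize_key(raw)
        prior = entries.get(key)
        if prior is not None and prior != generic:
            raise ValueError(f"conflicting dictionary entries for key {key!r}: "
                             f"{prior} vs {generic}")
        entries[key] = generic
    return DrugDictionary(entries=entries)


def normalize_name(raw_name: str, dictionary: DrugDictionary) -> Optional[str]:
    """Map a raw drug-name string to its generic; ``None`` when unmapped."""
    return dictionary.entries.get(normalize_key(raw_name))


@dataclass
class MappingReport:
    n_entries: int = 0
    n_ps: int = 0
    n_ps_mapped: int = 0
    unmapped: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {"n_entries": self.n_entries, "n_ps": self.n_ps,
                "n_ps_mapped": self.n_ps_mapped,
                "n_unmapped_ps_names": len(self.unmapped)}


def select_primary_suspect(drug: pd.DataFrame, dictionary: DrugDictionary
                           ) -> Tuple[pd.DataFrame, MappingReport]:
    """Select primary-suspect statin exposures from a validated DRUG frame.

    Only rows with role ``PS`` whose name maps to a statin generic are
    returned, as a frame with columns ``primaryid, drug_seq, generic,
    dose_amount, dose_unit, dose_frequency``.  A case may legitimately carry
    more than one PS statin; all are kept.
    """
    report = MappingReport(n_entries=len(drug))
    ps = drug[drug["role"] == "PS"]
    report.n_ps = len(ps)
    if ps.empty:
        empty = pd.DataFrame(columns=["primaryid", "drug_seq", "generic",
                                      "dose_amount", "dose_unit",
                                      "dose_frequency"])
        return empty, report
    keys = ps["raw_name"].map(normalize_key)
    generic = keys.map(dictionary.entries)
    unmapped_keys = keys[generic.isna()]
    report.unmapped.update(unmapped_keys)
    out = ps.loc[generic.notna(),
                 ["primaryid", "drug_seq", "dose_amount", "dose_unit",
                  "dose_frequency"]].copy()
    out["generic"] = generic[generic.notna()]
    report.n_ps_mapped = len(out)
    cols = ["primaryid", "drug_seq", "generic", "dose_amount", "dose_unit",
            "dose_frequency"]
    return out[cols].reset_index(drop=True), report


def ps_statin_sets(ps_frame: pd.DataFrame) -> Dict[str, Set[str]]:
    """{primaryid: set of PS statin generics} from ``select_primary_suspect``."""
    return {pid: set(grp) for pid, grp in
            ps_frame.groupby("primaryid")["generic"]}
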