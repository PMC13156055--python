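"""In-memory containers for spontaneous adverse-event reports.

A report collection mirrors the three tables a spontaneous-reporting
database exposes: demographics (one row per report version), drug
mentions with role codes, and adverse-event mentions coded as MedDRA
preferred terms (PTs).  The containers are thin wrappers over pandas
DataFrames so that counting operations downstream stay vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

DEMO_COLUMNS = ["primaryid", "caseid", "age", "sex", "country"]
DRUG_COLUMNS = ["primaryid", "drugname", "canonical", "role"]
REAC_COLUMNS = ["primaryid", "pt"]

#: FAERS role codes: primary suspect, secondary suspect, interacting, concomitant.
ROLE_CODES = ("PS", "SS", "I", "C")


@dataclass
class Provenance:
    """Row-count bookkeeping carried through every pipeline stage."""

    raw_reports: int = 0
    dropped_no_event: int = 0
    duplicates_removed: int = 0
    unmapped_drug_names: int = 0
    orphan_drug_rows: int = 0
    orphan_reac_rows: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "raw_reports": self.raw_reports,
            "dropped_no_event": self.dropped_no_event,
            "duplicates_removed": self.duplicates_removed,
            "unmapped_drug_names": self.unmapped_drug_names,
            "orphan_drug_rows": self.orphan_drug_rows,
            "orphan_reac_rows": self.orphan_reac_rows,
        }


@dataclass(frozen=True)
class DrugMention:
    raw_name: str
    canonical: str | None
    role: str


@dataclass(frozen=True)
class Report:
    """One deduplicated spontaneous report (row view over a ReportSet)."""

    primaryid: int
    caseid: int
    age: float | None
    sex: str | None
    country: str | None
    drugs: tuple[DrugMention, ...]
    events: frozenset[str]


@dataclass
class ReportSet:
    """A collection of spontaneous reports plus provenance counters.

    ``demo`` has one row per report (primaryid, caseid, age, sex,
    country); ``drugs`` and ``events`` are long-format mention tables
    keyed by primaryid.  Missing demographics are NaN/None.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        for frame, cols in ((self.demo, DEMO_COLUMNS), (self.drugs, DRUG_COLUMNS), (self.events, REAC_COLUMNS)):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ValueError(f"report table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.demo)

    @property
    def primaryids(self) -> pd.Series:
        return self.demo["primaryid"]

    def subset(self, primaryids) -> "ReportSet":
        """Restrict to the given primaryids, preserving provenance."""
        ids = pd.Index(primaryids)
        return ReportSet(
            demo=self.demo[self.demo["primaryid"].isin(ids)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["primaryid"].isin(ids)].reset_index(drop=True),
            events=self.events[self.events["primaryid"].isin(ids)].reset_index(drop=True),
            provenance=replace(self.provenance),
        )

    def iter_reports(self) -> Iterator[Report]:
        """Yield Report objects; convenient for tests and small data."""
        drug_groups = {pid: g for pid, g in self.drugs.groupby("primaryid")}
        event_groups = {pid: set(g["pt"]) for pid, g in self.events.groupby("primaryid")}
        for row in self.demo.itertuples(index=False):
            g = drug_groups.get(row.primaryid)
            mentions: tuple[DrugMention, ...] = ()
            if g is not None:
                mentions = tuple(
                    DrugMention(
                        raw_name=r.drugname,
                        canonical=None if pd.isna(r.canonical) else r.canonical,
                        role=r.role,
                    )
                    for r in g.itertuples(index=False)
                )
            yield Report(
                primaryid=int(row.primaryid),
                caseid=int(row.caseid),
                age=None if pd.isna(row.age) else float(row.age),
                sex=None if pd.isna(row.sex) else str(row.sex),
                country=None if pd.isna(row.country) else str(row.country),
                drugs=mentions,
                events=frozenset(event_groups.get(row.primaryid, set())),
            )

    def ps_primaryids(self, canonical_drug: str) -> np.ndarray:
        """Primaryids where ``canonical_drug`` is the primary suspect."""
        mask = (self.drugs["canonical"] == canonical_drug) & (self.drugs["role"] == "PS")
        return self.drugs.loc[mask, "primaryid"].unique()

    def event_primaryids(self, pts) -> np.ndarray:
        """Primaryids reporting at least one PT from ``pts``."""
        mask = self.events["pt"].isin(set(pts))
        return self.events.loc[mask, "primaryid"].unique()
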